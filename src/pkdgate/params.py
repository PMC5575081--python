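"""Channel parameter sets for the PKD2L1 gating model.

PKD2L1 is a weakly voltage-dependent TRP-family channel whose macroscopic
current is described here by a single Hodgkin–Huxley-style activation
variable.  This module holds the per-channel parameter tables for the
wild-type channel and the three S4 charge-neutralising mutants (K452Q,
K455Q, K461Q):

* steady-state activation — a Boltzmann curve with a constitutive (basal)
  open fraction,
* voltage-dependent activation/deactivation time constants, split into a
  depolarised branch (V >= 0 mV) and a hyperpolarised branch (V < 0 mV),
* single-channel rectification — inward and outward unitary slope
  conductances around a common reversal potential,
* shared model constants (maximal conductance, reversal potential,
  temperature).

Parameter bundles are plain frozen dataclasses so they serialise cleanly to
the JSON configuration format (see :func:`load_model_config`).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from scipy import constants as _const

__all__ = [
    "ChannelType",
    "ActivationParams",
    "DepolTauBranch",
    "HyperpolTauBranch",
    "TimeConstantSpec",
    "ModelConstants",
    "RectificationProfile",
    "ChannelModel",
    "builtin_model",
    "thermal_voltage_mv",
    "load_model_config",
    "dump_model_config",
]


def thermal_voltage_mv(temperature_k: float) -> float:
    """Thermal voltage k_B*T/e in mV (25.69 mV at 298.15 K).

    Always derived from the absolute temperature; never set directly.
    """
    if not (temperature_k > 0):
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1000.0 * _const.k * temperature_k / _const.e


class ChannelType(str, enum.Enum):
    """The four channel variants with built-in parameter tables."""

    WT = "WT"
    K452Q = "K452Q"
    K455Q = "K455Q"
    K461Q = "K461Q"

    @classmethod
    def coerce(cls, value: "ChannelType | str") -> "ChannelType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValueError(
                f"unknown channel type {value!r}; built-ins are "
                f"{[c.value for c in cls]} — supply explicit parameters "
                "for other channels"
            ) from None


@dataclass(frozen=True)
class ActivationParams:
    """Steady-state activation Boltzmann: basal + amplitude / (1 + exp(-s (V - V1/2))).

    ``slope_inv_mv`` is the combined valence/thermal factor z/(k_B T) in
    1/mV; multiplying by the thermal voltage gives the apparent valence in
    elementary charges.  ``basal`` is the constitutive open fraction that
    persists at strongly hyperpolarised potentials.
    """

    v_half: float
    slope_inv_mv: float
    basal: float = 0.02
    amplitude: float = 0.98

    def __post_init__(self) -> None:
        if not (self.slope_inv_mv > 0):
            raise ValueError(f"slope_inv_mv must be > 0, got {self.slope_inv_mv}")
        if not (0.0 <= self.basal < 1.0):
            raise ValueError(f"basal must be in [0, 1), got {self.basal}")
        if not (self.amplitude > 0):
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.basal + self.amplitude > 1.0 + 1e-9:
            raise ValueError(
                f"basal + amplitude must not exceed 1, got {self.basal + self.amplitude}"
            )


@dataclass(frozen=True)
class DepolTauBranch:
    """Time-constant family for V >= 0 mV.

    form = "logistic":         tau = amplitude / (1 + exp(rate * (V - center)))
    form = "logistic-literal": tau = amplitude / (1 + exp(rate * V - center))

    The "literal" form exists because the published K452Q expression is
    60.6/(1 + exp(0.008 V - 70)), which is numerically a near-constant
    60.6 ms; the parenthesised reading 60.6/(1 + exp(0.008 (V - 70))) is
    available behind a configuration switch (see :func:`builtin_model`).
    """

    form: str
    amplitude_ms: float
    rate_per_mv: float
    center_mv: float

    _FORMS = ("logistic", "logistic-literal")

    def __post_init__(self) -> None:
        if self.form not in self._FORMS:
            raise ValueError(f"form must be one of {self._FORMS}, got {self.form!r}")
        if not (self.amplitude_ms > 0):
            raise ValueError("amplitude_ms must be > 0")

    def tau(self, v: float) -> float:
        if self.form == "logistic":
            arg = self.rate_per_mv * (v - self.center_mv)
        else:
            arg = self.rate_per_mv * v - self.center_mv
        return self.amplitude_ms / (1.0 + math.exp(arg))


@dataclass(frozen=True)
class HyperpolTauBranch:
    """Time-constant family for V < 0 mV.

    tau = offset + amplitude * exp(-rate * (V + shift))

    With offset = shift = 0 this is a pure exponential; the K461Q channel
    uses a non-zero offset (deactivation saturates near 1.33 ms).
    """

    offset_ms: float
    amplitude_ms: float
    rate_per_mv: float
    shift_mv: float

    def __post_init__(self) -> None:
        if self.offset_ms < 0 or self.amplitude_ms < 0:
            raise ValueError("offset_ms and amplitude_ms must be >= 0")
        if self.offset_ms == 0 and self.amplitude_ms == 0:
            raise ValueError("branch would be identically zero")

    def tau(self, v: float) -> float:
        return self.offset_ms + self.amplitude_ms * math.exp(
            -self.rate_per_mv * (v + self.shift_mv)
        )


@dataclass(frozen=True)
class TimeConstantSpec:
    """Per-channel tau(V): depolarised branch for V >= 0, hyperpolarised for V < 0.

    The two branches generally do not meet at V = 0 (e.g. WT: 20.16 ms from
    the right, 10.9 ms from the left); the discontinuity is intentional and
    reproduces the published piecewise definition exactly.
    """

    channel: str
    depol_branch: DepolTauBranch
    hyperpol_branch: HyperpolTauBranch


@dataclass(frozen=True)
class ModelConstants:
    """Shared macroscopic constants.

    g_max is the maximal conductance density in nS/pF.  Its absolute value
    is not identifiable from normalised-tail analysis and defaults to 1;
    every fitting procedure in this package is invariant to it.
    """

    g_max: float = 1.0
    e_rev: float = 11.64
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.g_max > 0):
            raise ValueError("g_max must be > 0")
        if not (self.temperature > 0):
            raise ValueError("temperature must be > 0")

    @property
    def kt_over_e(self) -> float:
        """Thermal voltage in mV, recomputed from temperature."""
        return thermal_voltage_mv(self.temperature)


@dataclass(frozen=True)
class RectificationProfile:
    """Single-channel inward rectification.

    gamma_in / gamma_out are the unitary slope conductances (pS) on the
    inward and outward limbs of the single-channel i–V; the limb break sits
    at the upper edge of ``inward_range``.  ``transition_width`` is the
    voltage scale of the logistic interpolation used for the macroscopic
    scaling factor SF(V).
    """

    gamma_in: float
    gamma_out: float
    e_rev: float = 11.64
    transition_width: float = 15.0
    inward_range: tuple[float, float] = (-100.0, 40.0)
    outward_range: tuple[float, float] = (40.0, 140.0)

    def __post_init__(self) -> None:
        if not (self.gamma_in > 0 and self.gamma_out > 0):
            raise ValueError("unitary conductances must be > 0")
        if not (self.transition_width > 0):
            raise ValueError("transition_width must be > 0")

    @property
    def ratio(self) -> float:
        """gamma_out / gamma_in; < 1 means inward rectification."""
        return self.gamma_out / self.gamma_in

    @property
    def limb_break(self) -> float:
        return self.inward_range[1]


@dataclass(frozen=True)
class ChannelModel:
    """Complete parameter bundle for one channel variant."""

    channel: str
    activation: ActivationParams
    tau: TimeConstantSpec
    rectification: RectificationProfile
    constants: ModelConstants = field(default_factory=ModelConstants)


# Half-activation voltage (mV) and z/kBT slope (1/mV) per channel.
_ACTIVATION_TABLE: dict[ChannelType, tuple[float, float]] = {
    ChannelType.WT: (138.3, 0.0249),
    ChannelType.K452Q: (295.0, 0.0234),
    ChannelType.K455Q: (280.0, 0.0233),
    ChannelType.K461Q: (182.7, 0.0217),
}

_DEPOL_TAU: dict[ChannelType, DepolTauBranch] = {
    ChannelType.WT: DepolTauBranch("logistic", 20.7, 0.025, 145.0),
    # literal-as-printed: exp(0.008 V - 70), effectively constant 60.6 ms
    ChannelType.K452Q: DepolTauBranch("logistic-literal", 60.6, 0.008, 70.0),
    ChannelType.K455Q: DepolTauBranch("logistic", 54.6, 0.0065, 25.0),
    ChannelType.K461Q: DepolTauBranch("logistic", 10.12, 0.0237, 125.2),
}

_K452Q_DEPOL_PARENTHESISED = DepolTauBranch("logistic", 60.6, 0.008, 70.0)

_HYPERPOL_TAU: dict[ChannelType, HyperpolTauBranch] = {
    ChannelType.WT: HyperpolTauBranch(0.0, 10.9, 0.001, 0.0),
    ChannelType.K452Q: HyperpolTauBranch(0.0, 1.7, 0.008, 69.1),
    ChannelType.K455Q: HyperpolTauBranch(0.0, 1.6, 0.008, 80.75),
    ChannelType.K461Q: HyperpolTauBranch(1.33, 0.16, 0.014, 0.0),
}

# Unitary slope conductances (pS): inward limb (-100..40 mV), outward limb
# (40..140 mV).  K452Q rectifies outward (ratio > 1).
_RECTIFICATION_TABLE: dict[ChannelType, tuple[float, float]] = {
    ChannelType.WT: (161.9, 102.4),
    ChannelType.K452Q: (117.3, 137.8),
    ChannelType.K455Q: (125.5, 77.0),
    ChannelType.K461Q: (184.3, 85.9),
}


def builtin_model(
    channel: ChannelType | str,
    *,
    constants: ModelConstants | None = None,
    k452q_tau_interpretation: str = "literal",
) -> ChannelModel:
    """Build the shipped parameter bundle for one of the four channel variants.

    Parameters
    ----------
    channel
        One of WT, K452Q, K455Q, K461Q.
    constants
        Override the shared constants (g_max, e_rev, temperature).
    k452q_tau_interpretation
        "literal" (default) keeps the published K452Q depolarised time
        constant exactly as printed, 60.6/(1+exp(0.008 V - 70)); the
        alternative "parenthesised" reads it as 60.6/(1+exp(0.008 (V - 70))).
    """
    ch = ChannelType.coerce(channel)
    if k452q_tau_interpretation not in ("literal", "parenthesised"):
        raise ValueError(
            "k452q_tau_interpretation must be 'literal' or 'parenthesised'"
        )
    v_half, slope = _ACTIVATION_TABLE[ch]
    depol = _DEPOL_TAU[ch]
    if ch is ChannelType.K452Q and k452q_tau_interpretation == "parenthesised":
        depol = _K452Q_DEPOL_PARENTHESISED
    constants = constants or ModelConstants()
    gamma_in, gamma_out = _RECTIFICATION_TABLE[ch]
    return ChannelModel(
        channel=ch.value,
        activation=ActivationParams(v_half=v_half, slope_inv_mv=slope),
        tau=TimeConstantSpec(ch.value, depol, _HYPERPOL_TAU[ch]),
        rectification=RectificationProfile(
            gamma_in=gamma_in, gamma_out=gamma_out, e_rev=constants.e_rev
        ),
        constants=constants,
    )


# ---------------------------------------------------------------------------
# JSON configuration


def _model_to_dict(model: ChannelModel) -> dict:
    d = model.tau.depol_branch
    h = model.tau.hyperpol_branch
    r = model.rectification
    return {
        "v_half": model.activation.v_half,
        "slope_inv_mv": model.activation.slope_inv_mv,
        "basal": model.activation.basal,
        "amplitude": model.activation.amplitude,
        "tau_depol": {
            "form": d.form,
            "amplitude_ms": d.amplitude_ms,
            "rate_per_mv": d.rate_per_mv,
            "center_mv": d.center_mv,
        },
        "tau_hyperpol": {
            "offset_ms": h.offset_ms,
            "amplitude_ms": h.amplitude_ms,
            "rate_per_mv": h.rate_per_mv,
            "shift_mv": h.shift_mv,
        },
        "rectification": {
            "gamma_in": r.gamma_in,
            "gamma_out": r.gamma_out,
            "e_rev": r.e_rev,
            "transition_width": r.transition_width,
            "inward_range": list(r.inward_range),
            "outward_range": list(r.outward_range),
        },
    }


def _model_from_dict(channel: str, cfg: dict, constants: ModelConstants) -> ChannelModel:
    td = cfg["tau_depol"]
    th = cfg["tau_hyperpol"]
    rc = cfg.get("rectification", {})
    rect = RectificationProfile(
        gamma_in=rc["gamma_in"],
        gamma_out=rc["gamma_out"],
        e_rev=rc.get("e_rev", constants.e_rev),
        transition_width=rc.get("transition_width", 15.0),
        inward_range=tuple(rc.get("inward_range", (-100.0, 40.0))),
        outward_range=tuple(rc.get("outward_range", (40.0, 140.0))),
    )
    return ChannelModel(
        channel=channel,
        activation=ActivationParams(
            v_half=cfg["v_half"],
            slope_inv_mv=cfg["slope_inv_mv"],
            basal=cfg.get("basal", 0.02),
            amplitude=cfg.get("amplitude", 0.98),
        ),
        tau=TimeConstantSpec(
            channel,
            DepolTauBranch(
                td["form"], td["amplitude_ms"], td["rate_per_mv"], td["center_mv"]
            ),
            HyperpolTauBranch(
                th["offset_ms"], th["amplitude_ms"], th["rate_per_mv"], th["shift_mv"]
            ),
        ),
        rectification=rect,
        constants=constants,
    )


def load_model_config(path: str | Path | None = None) -> dict[str, ChannelModel]:
    """Load a model configuration JSON; None loads the shipped defaults.

    Schema: {"constants": {g_max, e_rev, temperature},
             "channels": {label: {v_half, slope_inv_mv, basal, amplitude,
                                  tau_depol, tau_hyperpol, rectification}}}
    """
    if path is None:
        text = (
            resources.files("pkdgate").joinpath("data/default_model.json").read_text()
        )
        raw = json.loads(text)
    else:
        raw = json.loads(Path(path).read_text())
    c = raw.get("constants", {})
    constants = ModelConstants(
        g_max=c.get("g_max", 1.0),
        e_rev=c.get("e_rev", 11.64),
        temperature=c.get("temperature", 298.15),
    )
    return {
        label: _model_from_dict(label, cfg, constants)
        for label, cfg in raw["channels"].items()
    }


def dump_model_config(models: dict[str, ChannelModel], path: str | Path) -> None:
    """Write a configuration JSON for a set of channel models.

    All models are assumed to share one ModelConstants (the first is used).
    """
    first = next(iter(models.values()))
    raw = {
        "constants": {
            "g_max": first.constants.g_max,
            "e_rev": first.constants.e_rev,
            "temperature": first.constants.temperature,
        },
        "channels": {label: _model_to_dict(m) for label, m in models.items()},
    }
    Path(path).write_text(json.dumps(raw, indent=2) + "\n")
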