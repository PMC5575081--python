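import pytest

from pkdgate import builtin_model


@pytest.fixture(scope="session")
def wt():
    return builtin_model("WT")


@pytest.fixture(scope="session")
def k461q():
    return builtin_model("K461Q")


@pytest.fixture(scope="session", params=["WT", "K452Q", "K455Q", "K461Q"])
def each_model(request):
    return builtin_model(request.param)
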