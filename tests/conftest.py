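import pytest

from stereorecip.core import ModelParams, default_params


@pytest.fixture
def sj_public() -> ModelParams:
    """Stern Judging, fully public monitoring, b=3, c=1, u=0.02."""
    return default_params()


@pytest.fixture
def sj_private() -> ModelParams:
    return default_params(individual_scale="private", stereotype_scale="private")


@pytest.fixture(params=["private", "group-wise", "public"])
def individual_scale(request) -> str:
    return request.param


@pytest.fixture(params=["private", "group-wise", "public"])
def stereotype_scale(request) -> str:
    return request.param


@pytest.fixture
def sj_combo(individual_scale, stereotype_scale) -> ModelParams:
    """Stern Judging under each of the nine monitoring combinations."""
    return default_params(
        individual_scale=individual_scale, stereotype_scale=stereotype_scale
    )


def scalar_fixed_point(update, lo=0.0, hi=1.0, tol=1e-12):
    """Independent bisection oracle for scalar fixed points g = F(g).

    Assumes F(g) - g changes sign on [lo, hi].
    """
    f = lambda g: update(g) - g
    flo = f(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(hi - lo) < tol:
            break
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)
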