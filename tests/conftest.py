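import itertools

import numpy as np
import pytest

import varaux as va


@pytest.fixture(scope="session")
def pop1():
    """Bundled fish-survey parameter set 1 (auxiliary = previous year)."""
    return va.load_fixture("population1")


@pytest.fixture(scope="session")
def pop2():
    """Bundled fish-survey parameter set 2 (auxiliary = two years prior)."""
    return va.load_fixture("population2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260904)


def random_population(rng, N=50, rho=0.8):
    """A correlated (y, x) population with a non-trivial moment structure."""
    x = rng.gamma(shape=3.0, scale=2.0, size=N)
    y = rho * x + rng.normal(0.0, 1.0 + 0.2 * np.sqrt(x), size=N)
    return va.PopulationFrame.from_xy(y=y, x=x)


@pytest.fixture()
def frame50(rng):
    return random_population(rng, N=50)


def brute_force_summary(y, x, rank_x):
    """Straight-loop reference for every MomentSet field (no numpy reductions
    beyond means); intentionally independent of the package implementation."""
    N = len(y)
    my = sum(y) / N
    mx = sum(x) / N
    mr = sum(rank_x) / N

    def v(r, s, t):
        total = 0.0
        for i in range(N):
            total += (y[i] - my) ** r * (x[i] - mx) ** s * (rank_x[i] - mr) ** t
        return total / (N - 1)

    def corr(a, b, ma, mb):
        num = sum((a[i] - ma) * (b[i] - mb) for i in range(N))
        da = sum((a[i] - ma) ** 2 for i in range(N)) ** 0.5
        db = sum((b[i] - mb) ** 2 for i in range(N)) ** 0.5
        return num / (da * db)

    v200, v020, v002 = v(2, 0, 0), v(0, 2, 0), v(0, 0, 2)
    out = {
        "Sy2": v200, "Sx2": v020, "Srx2": v002,
        "mean_y": my, "mean_x": mx, "mean_rx": mr,
        "rho_yx": corr(y, x, my, mx),
        "rho_yrx": corr(y, rank_x, my, mr),
        "rho_xrx": corr(x, rank_x, mx, mr),
    }
    for base in ("400", "040", "004", "220", "202", "022"):
        r, s, t = (int(c) for c in base)
        lam = v(r, s, t) / (v200 ** (r / 2) * v020 ** (s / 2) * v002 ** (t / 2))
        out[f"lam{base}"] = lam
        out[f"lam{base}s"] = lam - 1.0
    out["rho_star"] = out["lam220s"] / (out["lam400s"] * out["lam040s"]) ** 0.5
    return out


def enumerate_samples(pop, n):
    """Every SRSWOR sample of size n, as SampleFrames (exhaustive oracle)."""
    for idx in itertools.combinations(range(pop.N), n):
        idx = list(idx)
        yield va.SampleFrame.from_units(pop.y[idx], pop.x[idx], pop.rank_x[idx])
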