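"""Shared fixtures: small hand-built objects and session-scoped simulations."""

import numpy as np
import pandas as pd
import pytest

import rbprofiler as rb


@pytest.fixture()
def toy_catalog() -> rb.RBPCatalog:
    cat = rb.compile_catalog(["g1", "g2", "g3"], ["g3", "g4"])
    cat = rb.annotate_rbds(
        cat, {"g1": ["RRM"], "g2": ["RRM", "zf-CCCH"], "g3": [], "g4": ["WD40"]}
    )
    cat = rb.assign_function_classes(
        cat,
        {"g1": {"translation"}, "g2": {"translation", "splicing"}},
    )
    return cat


def _meta(samples, cell_types, subsets=None, donors=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "cell_type": cell_types,
            "subset": subsets or cell_types,
            "donor": donors or [f"d{i}" for i in range(n)],
        },
        index=pd.Index(samples, name="sample"),
    )


@pytest.fixture()
def small_counts() -> rb.ExpressionMatrix:
    values = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100],
            "s2": [20, 0, 10, 200],
            "s3": [12, 1, 6, 110],
            "s4": [18, 0, 9, 190],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return rb.ExpressionMatrix(
        values, _meta(values.columns, ["B", "B", "T", "T"]), unit="counts"
    )


@pytest.fixture(scope="session")
def bulk_null():
    em, truth = rb.simulate_bulk(n_genes=2000, de_fraction=0.0, seed=2)
    return em, truth


@pytest.fixture(scope="session")
def bulk_planted():
    em, truth = rb.simulate_bulk(n_genes=2000, de_fraction=0.1, de_lfc=2.0, seed=3)
    return em, truth


@pytest.fixture(scope="session")
def sc_default():
    return rb.simulate_sc(seed=0)


@pytest.fixture(scope="session")
def scored_default(sc_default):
    sc, truth = sc_default
    scorer = rb.CytotoxicScorer().fit(sc)
    return scorer, truth


def hurdle_grid_oracle(values, groups):
    """Grid-search ML oracle for the two-part hurdle model on one gene.

    Detection rates, Gaussian means and the shared sd are maximised
    over fine grids instead of in closed form; returns the combined
    likelihood-ratio statistic.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    det = v > 0
    rates = np.linspace(1e-4, 1 - 1e-4, 4001)

    def bern_ll(k, n, p):
        return k * np.log(p) + (n - k) * np.log1p(-p)

    lr = 0.0
    k1, n1 = det[g == "a"].sum(), (g == "a").sum()
    k2, n2 = det[g == "b"].sum(), (g == "b").sum()
    if 0 < k1 + k2 < n1 + n2:
        ll_full = max(bern_ll(k1, n1, p) for p in rates) + max(
            bern_ll(k2, n2, p) for p in rates
        )
        ll_null = max(bern_ll(k1 + k2, n1 + n2, p) for p in rates)
        lr += 2 * (ll_full - ll_null)

    a = v[(g == "a") & det]
    b = v[(g == "b") & det]
    pos = np.concatenate([a, b])
    if a.size >= 1 and b.size >= 1 and pos.size >= 3 and pos.std() > 0:
        mgrid = np.linspace(pos.min() - 1, pos.max() + 1, 401)
        sgrid = np.linspace(1e-3, 2 * pos.std() + 1, 401)

        def norm_ll(x, m, s):
            return -x.size * np.log(s) - ((x - m) ** 2).sum() / (2 * s**2)

        ll_full = max(
            max(norm_ll(a, m1, s) for m1 in mgrid)
            + max(norm_ll(b, m2, s) for m2 in mgrid)
            for s in sgrid
        )
        ll_null = max(max(norm_ll(pos, m, s) for m in mgrid) for s in sgrid)
        lr += 2 * (ll_full - ll_null)
    return lr


@pytest.fixture(scope="session")
def sc_null_groups():
    """Null single-cell data (no latent activity) with random 200/200 split."""
    sc, truth = rb.simulate_sc(
        n_cells=400, n_genes=1000, latent_sd=0.0, naive_fraction=0.0, seed=7
    )
    rng = np.random.default_rng(107)
    labels = pd.Series(
        np.where(rng.permutation(400) < 200, "low", "high"), index=sc.cells
    )
    return sc, labels
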