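"""Renormalization, aggregation, the Levene-gated test chain, and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmsi import synthetic_data as sd
from lipidmsi.fingerprint_stats import (
    AnnotatedFingerprint,
    anova_oneway,
    average_hemispheres,
    class_abundance,
    compare_groups,
    fa_pool_abundance,
    games_howell,
    levene_test,
    pca,
    renormalize_annotated,
    stars,
    tukey_hsd,
)
from lipidmsi.lipid_db import Annotation, AnnotationCandidate, annotate_channels, build_database


def fake_annotations(labels):
    """Annotations carrying given labels (None = unmatched) without a database."""

    class _Ann:
        def __init__(self, label):
            self._label = label

        @property
        def matched(self):
            return self._label is not None

        @property
        def label(self):
            return self._label

    return [_Ann(l) for l in labels]


def test_renormalize_drops_unannotated_and_scales():
    fp = np.array([0.3, 0.6, 0.1])
    anns = fake_annotations(["PI 38:4", None, "PC 34:1"])
    out = renormalize_annotated(fp, anns)
    assert out.abundances == pytest.approx({"PI 38:4": 0.75, "PC 34:1": 0.25})


def test_renormalize_identity_when_all_annotated_and_unit_sum():
    fp = np.array([0.25, 0.75])
    out = renormalize_annotated(fp, fake_annotations(["PI 38:4", "PC 34:1"]))
    assert out.abundances == pytest.approx({"PI 38:4": 0.25, "PC 34:1": 0.75})


def test_renormalize_merges_channels_with_same_label():
    out = renormalize_annotated(
        np.array([0.1, 0.3, 0.6]), fake_annotations(["PI 38:4", "PI 38:4", "PC 34:1"])
    )
    assert out.abundances == pytest.approx({"PI 38:4": 0.4, "PC 34:1": 0.6})


def test_renormalize_errors_without_annotated_signal():
    with pytest.raises(ValueError, match="no annotated"):
        renormalize_annotated(np.array([1.0]), fake_annotations([None]))
    with pytest.raises(ValueError, match="no annotated"):
        renormalize_annotated(np.array([0.0]), fake_annotations(["PI 38:4"]))


@settings(deadline=None, max_examples=100)
@given(
    st.lists(st.floats(1e-6, 1e3), min_size=1, max_size=30),
    st.data(),
)
def test_renormalized_sum_is_one(values, data):
    n = len(values)
    labels = [f"S {i}:0" if data.draw(st.booleans()) else None for i in range(n)]
    if not any(labels):
        labels[0] = "S 0:0"
    out = renormalize_annotated(np.array(values), fake_annotations(labels))
    assert sum(out.abundances.values()) == pytest.approx(1.0, abs=1e-9)


def _design(rows):
    return pd.DataFrame(rows, columns=["sample", "animal", "sex", "nucleus", "section",
                                       "hemisphere"])


def test_average_hemispheres_mean_and_identity():
    table = pd.DataFrame(
        [[0.6, 0.4], [0.4, 0.6], [0.3, 0.7], [0.3, 0.7]],
        index=["a-L", "a-R", "b-L", "b-R"],
        columns=["PI 38:4", "PC 34:1"],
    )
    design = _design([
        ["a-L", "a1", "F", "LC", 1, "L"],
        ["a-R", "a1", "F", "LC", 1, "R"],
        ["b-L", "a2", "M", "LC", 1, "L"],
        ["b-R", "a2", "M", "LC", 1, "R"],
    ])
    out = average_hemispheres(table, design)
    np.testing.assert_allclose(out.loc["a1/LC/1"], [0.5, 0.5])
    np.testing.assert_allclose(out.loc["a2/LC/1"], [0.3, 0.7])
    assert list(out.attrs["design"]["sex"]) == ["F", "M"]


def test_average_hemispheres_singleton_passes_through_with_warning():
    table = pd.DataFrame([[0.6, 0.4]], index=["a-L"], columns=["PI 38:4", "PC 34:1"])
    design = _design([["a-L", "a1", "F", "LC", 1, "L"]])
    with pytest.warns(UserWarning, match="unmatched hemisphere"):
        out = average_hemispheres(table, design)
    np.testing.assert_allclose(out.iloc[0], [0.6, 0.4])


def test_class_abundance_sums_species():
    fp = AnnotatedFingerprint({"PI 38:4": 0.2, "PC 34:1": 0.8})
    out = class_abundance(fp)
    assert out.to_dict() == pytest.approx({"PI": 0.2, "PC": 0.8})


def test_class_abundance_single_class_totals_one():
    fp = AnnotatedFingerprint({"SM 36:1": 0.4, "SM 42:2": 0.6})
    out = class_abundance(fp)
    assert out.to_dict() == pytest.approx({"SM": 1.0})


def test_class_abundance_preserves_total(rng):
    vals = rng.dirichlet(np.ones(10))
    labels = [f"PI 38:{i}" for i in range(5)] + [f"PC 34:{i}" for i in range(5)]
    fp = AnnotatedFingerprint(dict(zip(labels, vals)))
    assert class_abundance(fp).sum() == pytest.approx(1.0, abs=1e-9)


def test_fa_pool_with_evidence():
    fp = AnnotatedFingerprint({"PS 40:6": 0.1, "PI 38:4": 0.9})
    evidence = {"PS 40:6": ("18:0", "22:6")}
    dha, report = fa_pool_abundance(fp, "22:6", evidence)
    assert dha == pytest.approx(0.1)
    aa, _ = fa_pool_abundance(fp, "20:4", evidence)
    assert aa == 0.0
    assert report["uncovered"] == ["PI 38:4"]


def test_fa_pool_empty_evidence_warns_and_returns_zero():
    fp = AnnotatedFingerprint({"PS 40:6": 1.0})
    with pytest.warns(UserWarning, match="no acyl evidence"):
        total, report = fa_pool_abundance(fp, "22:6", {})
    assert total == 0.0 and report["coverage"] == 0.0


# --- test chain ------------------------------------------------------------


def levene_oracle(groups):
    """Textbook mean-centered Levene W, computed from the definition."""
    k = len(groups)
    z = [np.abs(np.asarray(g) - np.mean(g)) for g in groups]
    n = [len(g) for g in groups]
    N = sum(n)
    zbar = np.concatenate(z).mean()
    zi = [zz.mean() for zz in z]
    num = sum(ni * (m - zbar) ** 2 for ni, m in zip(n, zi)) / (k - 1)
    den = sum(((zz - m) ** 2).sum() for zz, m in zip(z, zi)) / (N - k)
    return num / den


def test_levene_equal_spread_shifted_groups():
    g1 = [1.0, 2.0, 3.0, 4.0]
    g2 = [11.0, 12.0, 13.0, 14.0]
    w, p = levene_test([g1, g2])
    assert w == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_levene_matches_definition_oracle(rng):
    groups = [rng.normal(0, s, n) for s, n in [(1, 7), (3, 9), (0.5, 5)]]
    w, p = levene_test(groups)
    assert w == pytest.approx(levene_oracle(groups), abs=1e-8)


def test_levene_detects_gross_variance_inequality(rng):
    hits = 0
    for i in range(100):
        r = np.random.default_rng(i)
        g1, g2 = r.normal(0, 1, 20), r.normal(0, 10, 20)
        _, p = levene_test([g1, g2])
        hits += p < 0.05
    assert hits >= 95


def test_anova_two_groups_equals_squared_t(rng):
    g1, g2 = rng.normal(0, 1, 10), rng.normal(0.8, 1, 14)
    f, p = anova_oneway([g1, g2])
    from scipy import stats

    t, pt = stats.ttest_ind(g1, g2, equal_var=True)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p == pytest.approx(pt, abs=1e-10)


def test_anova_zero_within_variance_p_zero():
    f, p = anova_oneway([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
    assert p == pytest.approx(0.0, abs=1e-12)


def test_tukey_identical_groups_p_one():
    g = [1.0, 2.0, 3.0]
    pw = tukey_hsd([g, g, g])
    assert all(p == pytest.approx(1.0, abs=1e-6) for p in pw.values())


def test_tukey_matches_pingouin(rng):
    import pingouin as pg

    groups = [rng.normal(0, 1, 8), rng.normal(0.7, 1, 10), rng.normal(1.2, 1, 6)]
    pw = tukey_hsd(groups)
    df = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat(["a", "b", "c"], [8, 10, 6]),
    })
    ref = pg.pairwise_tukey(dv="y", between="g", data=df).set_index(["A", "B"])["p_tukey"]
    assert pw[(0, 1)] == pytest.approx(ref[("a", "b")], abs=1e-6)
    assert pw[(0, 2)] == pytest.approx(ref[("a", "c")], abs=1e-6)
    assert pw[(1, 2)] == pytest.approx(ref[("b", "c")], abs=1e-6)


def test_tukey_two_groups_agrees_with_pooled_t(rng):
    g1, g2 = rng.normal(0, 1, 9), rng.normal(0.5, 1, 9)
    from scipy import stats

    pw = tukey_hsd([g1, g2])
    _, pt = stats.ttest_ind(g1, g2, equal_var=True)
    assert pw[(0, 1)] == pytest.approx(pt, abs=1e-8)


def test_games_howell_identical_groups_p_one():
    g = [1.0, 2.0, 3.0, 4.0]
    pw = games_howell([g, g])
    assert pw[(0, 1)] == pytest.approx(1.0, abs=1e-6)


def test_games_howell_matches_pingouin(rng):
    import pingouin as pg

    groups = [rng.normal(0, 1, 8), rng.normal(0.5, 3, 12), rng.normal(1, 0.5, 6)]
    pw = games_howell(groups)
    df = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat(["a", "b", "c"], [8, 12, 6]),
    })
    ref = pg.pairwise_gameshowell(dv="y", between="g", data=df).set_index(["A", "B"])["pval"]
    for (i, j), key in [((0, 1), ("a", "b")), ((0, 2), ("a", "c")), ((1, 2), ("b", "c"))]:
        assert pw[(i, j)] == pytest.approx(ref[key], abs=1e-6)


def test_games_howell_approaches_tukey_with_equal_variances(rng):
    groups = [rng.normal(m, 1, 500) for m in (0.0, 0.1, 0.2)]
    gh = games_howell(groups)
    tk = tukey_hsd(groups)
    for k in gh:
        assert gh[k] == pytest.approx(tk[k], abs=0.01)


def test_stars_thresholds():
    assert stars(0.2) == ""
    assert stars(0.04) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"


def _cohort_classes(cfg):
    table, design = sd.sample_cohort_fingerprints(cfg)
    avg = average_hemispheres(table, design)
    from lipidmsi.lipid_db import species_class

    classes = avg.T.groupby(
        pd.Index([species_class(s) for s in avg.columns], name="class")
    ).sum().T
    return classes, avg.attrs["design"]


def test_compare_groups_gate_routes_heteroscedastic_features():
    rng = np.random.default_rng(0)
    n = 12
    table = pd.DataFrame({
        "homo": np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)]),
        "hetero": np.concatenate([rng.normal(0, 0.05, n), rng.normal(0, 5, n)]),
    }, index=[f"s{i}" for i in range(2 * n)])
    design = pd.DataFrame({
        "sample": table.index,
        "sex": ["F"] * n + ["M"] * n,
    }).set_index("sample")
    res = {r.feature: r for r in compare_groups(table, design, "sex")}
    assert res["hetero"].posthoc == "Games-Howell"
    assert res["homo"].posthoc == "Tukey"
    assert res["hetero"].levene_p < 0.05 <= res["homo"].levene_p


def test_compare_groups_skips_small_groups():
    table = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
    design = pd.DataFrame({"sex": ["F", "F", "M"]}, index=["a", "b", "c"])
    res = compare_groups(table, design, "sex")
    assert res[0].skipped == "a group has n < 2"


def test_compare_groups_detects_planted_sm_effect():
    classes, design = _cohort_classes(sd.CohortConfig(class_effects={"SM": 0.7}, seed=9))
    res = {r.feature: r for r in compare_groups(classes, design, "sex")}
    assert any(c.p < 0.05 for c in res["SM"].pairwise)


def test_compare_groups_gate_is_function_of_levene_p():
    classes, design = _cohort_classes(sd.CohortConfig(seed=3))
    for r in compare_groups(classes, design, "sex"):
        if r.skipped:
            continue
        assert r.posthoc == ("Games-Howell" if r.levene_p < 0.05 else "Tukey")


# --- PCA ---------------------------------------------------------------------


def test_pca_rank_one_single_component_explains_all(rng):
    base = rng.uniform(0, 1, 5)
    table = pd.DataFrame(np.outer([1.0, 2.0, 3.0, 4.0], base))
    res = pca(table, scale01=True)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_scores_reconstruct_scaled_centered_data(rng):
    x = rng.uniform(0, 5, (8, 4))
    table = pd.DataFrame(x)
    res = pca(table, scale01=True)
    scaled = (x - x.min(0)) / np.ptp(x, axis=0)
    centered = scaled - scaled.mean(0)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    np.testing.assert_allclose(recon, centered, atol=1e-8)


def test_pca_explained_variance_properties(rng):
    table = pd.DataFrame(rng.uniform(0, 1, (10, 6)))
    res = pca(table)
    evr = res.explained_variance_ratio
    assert np.all(np.diff(evr) <= 1e-12)
    assert evr.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all((0 <= evr) & (evr <= 1))


def test_pca_sign_convention_deterministic(rng):
    x = rng.uniform(0, 1, (9, 5))
    r1, r2 = pca(pd.DataFrame(x)), pca(pd.DataFrame(x.copy()))
    np.testing.assert_allclose(r1.scores, r2.scores)
    for c in r1.loadings.columns:
        j = r1.loadings[c].abs().idxmax()
        assert r1.loadings.loc[j, c] >= 0


def test_pca_constant_feature_maps_to_zero():
    table = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 0.5, 1.0], "c": [3.0, 1.0, 2.0]})
    res = pca(table)
    assert res.feature_range["a"] == 0.0
    np.testing.assert_allclose(res.loadings.loc["a"].abs(), 0.0, atol=1e-12)


def test_pca_separates_three_nucleus_cohort():
    """Distinct planted nucleus profiles separate on the first two components."""
    from sklearn.metrics import silhouette_score

    frames, labels = [], []
    for nucleus, arch in [("LC", sd.lc_like()), ("Me5", sd.me5_like()), ("SNc", sd.snc_like())]:
        cfg = sd.CohortConfig(nucleus=nucleus, seed=hash(nucleus) % 1000)
        pcfg = sd.PhantomConfig(archetypes=(arch,), seed=cfg.seed)
        table, design = sd.sample_cohort_fingerprints(cfg, pcfg)
        avg = average_hemispheres(table, design)
        avg.attrs = {}  # design frame in attrs breaks pd.concat equality checks
        frames.append(avg)
        labels += [nucleus] * len(avg)
    table = pd.concat(frames)
    res = pca(table, scale01=True)
    score = silhouette_score(res.scores.iloc[:, :2], labels)
    assert score > 0.5
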