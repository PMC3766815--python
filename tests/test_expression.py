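"""Expression filtering, factor-adjusted DE, signatures, and overlap."""

import numpy as np
import pandas as pd
import pytest

from circafly import (ExpressionStudy, differential_expression,
                      filter_expressed, reference_interval, select_signature,
                      signature_overlap)
from circafly.expression import read_expression_tsv, write_expression_tsv
from circafly.synthetic import ExpressionSimSpec, simulate_expression


def small_study(matrix_rows, genes=None, reps=2):
    cols, rows = [], []
    for geno in ("mutant", "control"):
        for tp in ("ZT3", "ZT15"):
            for r in range(1, reps + 1):
                cols.append(f"{geno}_{tp}_r{r}")
                rows.append({"sample": cols[-1], "genotype": geno,
                             "timepoint": tp, "replicate": r})
    genes = genes or [f"g{i}" for i in range(len(matrix_rows))]
    matrix = pd.DataFrame(matrix_rows, index=pd.Index(genes, name="gene"),
                          columns=cols)
    return ExpressionStudy(matrix, pd.DataFrame(rows).set_index("sample"))


def test_expression_floor_quantifier_semantics():
    study = small_study([
        [4.1] * 4 + [3.2] * 4,   # all mutant above, all control below -> in
        [3.9] * 8,               # everything below -> out
        [4.5, 3.9, 4.5, 4.5, 4.5, 3.9, 4.5, 4.5],  # both groups mixed -> out
        [4.0] * 8,               # exactly at the floor: strict, out
    ])
    flags = filter_expressed(study)
    assert flags.tolist() == [True, False, False, False]


def test_expression_floor_matches_brute_force_any_all():
    rng = np.random.default_rng(3)
    study = small_study(rng.uniform(3.0, 5.0, size=(200, 8)))
    flags = filter_expressed(study)
    mut = study.group_columns("mutant")
    ctl = study.group_columns("control")
    for gene in study.matrix.index:
        row = study.matrix.loc[gene]
        expected = (all(row[c] > 4.0 for c in mut)
                    or all(row[c] > 4.0 for c in ctl))
        assert flags[gene] == expected


def test_identical_groups_give_null_de_result():
    vals = np.tile([6.0, 6.5, 7.0, 7.5], (3, 2))  # mutant == control
    study = small_study(vals)
    res = differential_expression(study)
    np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
    np.testing.assert_allclose(res["f_stat"], 0.0, atol=1e-9)
    np.testing.assert_allclose(res["p_value"], 1.0)


def test_de_matches_statsmodels_anova_per_gene():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    study, _, _ = simulate_expression(
        ExpressionSimSpec(n_genes=30, n_up=5, n_down=5, floor_fraction=0.0,
                          seed=5))
    res = differential_expression(study)
    long = study.matrix.T.join(study.samples)
    for gene in res.index[:15]:
        df = long[[gene, "genotype", "timepoint"]].rename(
            columns={gene: "y"})
        fit = smf.ols("y ~ C(genotype) + C(timepoint)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.loc[gene, "f_stat"] == pytest.approx(
            table.loc["C(genotype)", "F"], rel=1e-8)
        assert res.loc[gene, "p_value"] == pytest.approx(
            table.loc["C(genotype)", "PR(>F)"], rel=1e-8)


def test_planted_fold_changes_recovered():
    spec = ExpressionSimSpec(n_genes=400, n_up=20, n_down=10,
                             planted_log2fc=2.0, noise_sd=0.1, seed=6)
    study, truth, _ = simulate_expression(spec)
    res = differential_expression(study)
    planted = truth["planted_up"] + truth["planted_down"]
    signs = np.array([1.0] * 20 + [-1.0] * 10)
    errs = res.loc[planted, "log2fc"].to_numpy() - signs * 2.0
    # per-gene standard error is noise_sd*sqrt(2/6) ~ 0.058, so 0.15 is a
    # ~2.6-sigma band per gene: demand near-complete coverage there and
    # complete coverage at the ~4-sigma band
    assert (np.abs(errs) <= 0.15).mean() >= 0.9
    assert np.abs(errs).max() <= 0.25


def test_null_p_values_are_uniform():
    from scipy import stats

    spec = ExpressionSimSpec(n_genes=1000, n_up=0, n_down=0,
                             floor_fraction=0.0, seed=7)
    study, _, _ = simulate_expression(spec)
    res = differential_expression(study)
    ks = stats.kstest(res["p_value"], "uniform")
    assert ks.pvalue > 0.01
    frac = (res["p_value"] < 0.05).mean()
    assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / len(res))


def test_q_values_dominate_p_values():
    study, _, _ = simulate_expression(ExpressionSimSpec(n_genes=300, seed=8))
    res = differential_expression(study)
    assert (res["q_value"] >= res["p_value"] - 1e-15).all()


def test_signature_threshold_semantics():
    res = pd.DataFrame(
        {
            "log2fc": [0.60, 2.0, 0.0, -0.7],
            "q_value": [0.03, 0.10, 0.001, 0.01],
        },
        index=pd.Index(["a", "b", "c", "d"], name="gene"),
    )
    sel = select_signature(res)
    assert "a" in sel.up_strict          # 1.52-fold, q 0.03
    assert "b" not in sel.strict and "b" in sel.up_lenient
    assert "c" not in sel.lenient        # no fold change at all
    assert "d" in sel.down_strict
    assert set(sel.strict) <= set(sel.lenient)


def test_reference_interval_matches_quantile_oracle():
    rng = np.random.default_rng(9)
    vals = rng.uniform(0, 1, 200)
    lo, hi = reference_interval(vals)
    assert lo == pytest.approx(np.quantile(vals, 0.005))
    assert hi == pytest.approx(np.quantile(vals, 0.995))
    assert 0.0 < lo < 0.05 and 0.95 < hi < 1.0

    sym = np.concatenate([vals, -vals])       # symmetric about zero
    lo, hi = reference_interval(sym)
    assert lo + hi == pytest.approx(2 * np.median(sym), abs=1e-10)

    z = rng.standard_normal(10000)
    lo, hi = reference_interval(z)
    assert lo == pytest.approx(-2.576, abs=0.08)
    assert hi == pytest.approx(2.576, abs=0.08)

    with pytest.raises(ValueError, match=">=100"):
        reference_interval(np.ones(50))


def test_overlap_null_signature_is_not_significant():
    rng = np.random.default_rng(10)
    universe = pd.Series(rng.normal(0, 0.5, 2000),
                         index=[f"g{i}" for i in range(2000)])
    sig = pd.Series(0.5, index=universe.index[1000:1050])
    # signature genes forced to reference fold change 0: never outside
    universe.iloc[1000:1050] = 0.0
    ov = signature_overlap(sig, universe, n_perm=2000, seed=1)
    assert ov.n_outside == 0 and ov.n_concordant == 0
    assert ov.permutation_p == 1.0


def test_overlap_counts_and_invariants():
    spec = ExpressionSimSpec(n_genes=2000, n_up=10, n_down=5,
                             ref_concordance=1.0, seed=11)
    study, truth, ref = simulate_expression(spec)
    res = differential_expression(study)
    sel = select_signature(res)
    ov = signature_overlap(res.loc[sel.lenient, "log2fc"], ref,
                           n_perm=2000, seed=2)
    assert ov.n_concordant <= ov.n_outside <= ov.n_signature
    assert 0 < ov.permutation_p <= 1
    assert ov.permutation_p < 0.01


def test_overlap_reproducible_under_seed_and_drops_missing():
    rng = np.random.default_rng(12)
    universe = pd.Series(rng.normal(0, 0.5, 500),
                         index=[f"g{i}" for i in range(500)])
    sig = pd.Series([3.0, -3.0, 1.0], index=["g1", "g2", "not_in_ref"])
    a = signature_overlap(sig, universe, n_perm=500, seed=7)
    b = signature_overlap(sig, universe, n_perm=500, seed=7)
    assert a.permutation_p == b.permutation_p
    assert a.n_signature == 2 and a.n_dropped == 1
    with pytest.raises(ValueError, match="no signature gene"):
        signature_overlap(pd.Series([1.0], index=["zz"]), universe)


def test_expression_tsv_round_trip(tmp_path):
    study, _, _ = simulate_expression(
        ExpressionSimSpec(n_genes=50, n_up=5, n_down=5, seed=13))
    write_expression_tsv(study, tmp_path / "m.tsv", tmp_path / "s.tsv")
    back = read_expression_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(back.matrix, study.matrix)
    pd.testing.assert_frame_equal(back.samples, study.samples)
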