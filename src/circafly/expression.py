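"""Differential expression with a time-of-day covariate and signature overlap.

The study design is two genotypes (mutant vs control) sampled at two
Zeitgeber times (ZT3 and ZT15).  Per gene, expression (log2 scale, already
normalized upstream) is modeled additively as

    log2(y) ~ genotype + timepoint

and the genotype effect is tested with the F statistic of that term, i.e.
an ANOVA controlling for the effect of time of day.  Genes enter the
analysis only if every sample of at least one genotype group exceeds a
log2 expression floor (4.0 by default).  P-values are Benjamini-Hochberg
adjusted across the expressed genes only.

Signatures are selected at a strict (q < 0.05) and a lenient (q < 0.15)
FDR level, both with a linear fold-change requirement |FC| > 1.5
(|log2FC| > log2 1.5).  Cross-experiment overlap against a reference
fold-change table is scored by counting signature genes whose reference
fold change falls outside the reference's central 99% empirical interval
with matching sign, with significance from a seeded same-size random gene
set permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENOTYPES = ("mutant", "control")
TIMEPOINTS = ("ZT3", "ZT15")
EXPRESSION_FLOOR = 4.0
STRICT_Q = 0.05
LENIENT_Q = 0.15
FOLD_THRESHOLD = 1.5


@dataclass
class ExpressionStudy:
    """Genes x samples log2 matrix plus the sample factor sheet.

    ``samples`` is indexed by sample id with columns ``genotype``
    (mutant/control), ``timepoint`` (ZT3/ZT15) and ``replicate``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    floor: float = EXPRESSION_FLOOR

    def __post_init__(self) -> None:
        missing = set(self.matrix.columns) ^ set(self.samples.index)
        if missing:
            raise ValueError(f"matrix columns and sample sheet disagree: {missing}")
        for col in ("genotype", "timepoint"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet needs a {col!r} column")
        bad_g = set(self.samples["genotype"]) - set(GENOTYPES)
        bad_t = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_g or bad_t:
            raise ValueError(f"unknown factor levels: {bad_g | bad_t}")
        cell_sizes = self.samples.groupby(
            ["genotype", "timepoint"], observed=True).size()
        if len(cell_sizes) != 4 or (cell_sizes < 2).any():
            raise ValueError(
                "need >=2 replicates in every genotype x timepoint cell"
            )

    def group_columns(self, genotype: str) -> list[str]:
        return list(self.samples.index[self.samples["genotype"] == genotype])


def filter_expressed(study: ExpressionStudy) -> pd.Series:
    """Expressed iff *all* samples of at least one genotype exceed the floor
    (strict inequality), per gene."""
    flags = pd.Series(False, index=study.matrix.index, name="expressed")
    for geno in GENOTYPES:
        cols = study.group_columns(geno)
        flags |= (study.matrix[cols] > study.floor).all(axis=1)
    return flags


def differential_expression(
    study: ExpressionStudy, interaction: bool = False
) -> pd.DataFrame:
    """Per-gene genotype effect, controlling for time of day.

    Returns a frame over expressed genes with log2fc (mutant - control
    difference of genotype marginal means), f_stat, p_value (F test of the
    genotype term in the additive model) and q_value (BH over expressed
    genes).  The optional interaction flag adds a genotype x timepoint term
    to the residual model; the genotype test remains the main-effect drop.
    """
    expressed = filter_expressed(study)
    genes = study.matrix.index[expressed]
    if len(genes) == 0:
        raise ValueError("no gene passes the expression floor")
    cols = list(study.matrix.columns)
    y = study.matrix.loc[genes, cols].to_numpy().T     # samples x genes
    g = (study.samples.loc[cols, "genotype"] == "mutant").to_numpy(float)
    tp = (study.samples.loc[cols, "timepoint"] == "ZT15").to_numpy(float)
    ones = np.ones_like(g)
    x_full = np.column_stack([ones, g, tp])
    if interaction:
        x_full = np.column_stack([x_full, g * tp])
    x_red = np.delete(x_full, 1, axis=1)

    def rss(x: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return np.einsum("ij,ij->j", resid, resid)

    rss_full, rss_red = rss(x_full), rss(x_red)
    df_resid = y.shape[0] - x_full.shape[1]
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    denom = rss_full / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom > 0, (rss_red - rss_full) / denom, 0.0)
    f = np.clip(f, 0.0, None)
    p = stats.f.sf(f, 1, df_resid)
    p = np.where(denom > 0, p, 1.0)       # identical groups: F=0, p=1

    # genotype marginal means: average the cell means over timepoints so an
    # unbalanced timepoint allocation cannot masquerade as a genotype effect
    cell_means = {}
    for gv in (1.0, 0.0):
        sel = [y[(g == gv) & (tp == tv)].mean(axis=0) for tv in (0.0, 1.0)]
        cell_means[gv] = np.mean(sel, axis=0)
    log2fc = cell_means[1.0] - cell_means[0.0]

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "f_stat": f,
            "p_value": p,
            "q_value": q,
            "expressed": True,
        },
        index=pd.Index(genes, name="gene"),
    )


@dataclass
class SignatureSelection:
    up_strict: list[str]
    down_strict: list[str]
    up_lenient: list[str]
    down_lenient: list[str]
    table: pd.DataFrame

    @property
    def strict(self) -> list[str]:
        return self.up_strict + self.down_strict

    @property
    def lenient(self) -> list[str]:
        return self.up_lenient + self.down_lenient


def select_signature(
    results: pd.DataFrame,
    strict_q: float = STRICT_Q,
    lenient_q: float = LENIENT_Q,
    fold_threshold: float = FOLD_THRESHOLD,
) -> SignatureSelection:
    """Up/down gene sets at strict and lenient FDR levels.

    The fold requirement is on the linear scale (|log2fc| > log2 of the
    threshold) and applies to both sets; direction comes from the sign of
    log2fc.  With nested q thresholds the strict set is a subset of the
    lenient one.
    """
    lfc_cut = np.log2(fold_threshold)
    fold_ok = results["log2fc"].abs() > lfc_cut
    up = results["log2fc"] > 0
    table = results.copy()
    table["selected_strict"] = fold_ok & (results["q_value"] < strict_q)
    table["selected_lenient"] = fold_ok & (results["q_value"] < lenient_q)

    def genes(mask: pd.Series) -> list[str]:
        return list(results.index[mask])

    return SignatureSelection(
        up_strict=genes(table["selected_strict"] & up),
        down_strict=genes(table["selected_strict"] & ~up),
        up_lenient=genes(table["selected_lenient"] & up),
        down_lenient=genes(table["selected_lenient"] & ~up),
        table=table,
    )


def reference_interval(
    reference_fc: pd.Series | np.ndarray, coverage: float = 0.99
) -> tuple[float, float]:
    """Central empirical interval containing ``coverage`` of the reference
    fold changes: the (1-coverage)/2 and 1-(1-coverage)/2 quantiles under
    the linear-interpolation convention."""
    vals = np.asarray(reference_fc, dtype=float)
    if vals.size < 100:
        raise ValueError("need >=100 reference fold changes for the interval")
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass
class SignatureOverlap:
    reference_label: str
    interval_lo: float
    interval_hi: float
    n_signature: int
    n_dropped: int
    n_outside: int
    n_concordant: int
    permutation_p: float
    n_perm: int
    seed: int


def _sample_index_sets(rng: np.random.Generator, n_universe: int, k: int,
                       n_perm: int, chunk: int = 1000) -> np.ndarray:
    """``n_perm`` index sets of size k drawn without replacement, vectorized
    via Gumbel-style random-key top-k in memory-bounded chunks."""
    out = np.empty((n_perm, k), dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n_universe))
        out[done : done + m] = np.argpartition(keys, k, axis=1)[:, :k]
        done += m
    return out


def signature_overlap(
    signature_fc: pd.Series,
    reference_fc: pd.Series,
    coverage: float = 0.99,
    n_perm: int = 10000,
    seed: int = 0,
    reference_label: str = "reference",
    return_null: bool = False,
):
    """Concordant-overlap test of a signature against a reference experiment.

    ``signature_fc``: study log2 fold changes indexed by gene (the
    signature); ``reference_fc``: the reference experiment's fold changes
    over its whole gene universe.  A signature gene counts as *outside*
    when its reference fold change escapes the reference's central
    ``coverage`` interval, and *concordant* when additionally the signs
    agree.  The null redraws same-size gene sets from the reference
    universe (keeping the observed study signs paired by position) and the
    p-value uses the add-one permutation estimator.  With ``return_null``
    the sampled null concordance counts are returned alongside the result
    (the statistic is discrete, so calibration studies need the null draws
    to form randomized tie-broken p-values).
    """
    sig = signature_fc.dropna()
    if sig.empty:
        raise ValueError("empty signature")
    matched = sig.index.intersection(reference_fc.index)
    n_dropped = len(sig) - len(matched)
    if n_dropped:
        logger.info("dropping %d signature genes absent from the reference",
                    n_dropped)
    if len(matched) == 0:
        raise ValueError("no signature gene present in the reference table")
    lo, hi = reference_interval(reference_fc, coverage)
    ref = reference_fc.loc[matched].to_numpy(dtype=float)
    study_sign = np.sign(sig.loc[matched].to_numpy(dtype=float))
    outside = (ref < lo) | (ref > hi)
    concord = outside & (np.sign(ref) == study_sign)
    n_outside, n_conc = int(outside.sum()), int(concord.sum())

    universe = reference_fc.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = _sample_index_sets(rng, universe.size, len(matched), n_perm)
    ref_null = universe[idx]                              # n_perm x k
    out_null = (ref_null < lo) | (ref_null > hi)
    conc_null = (out_null & (np.sign(ref_null) == study_sign[None, :])).sum(axis=1)
    p = (1 + int(np.sum(conc_null >= n_conc))) / (n_perm + 1)
    result = SignatureOverlap(
        reference_label=reference_label,
        interval_lo=lo,
        interval_hi=hi,
        n_signature=int(len(matched)),
        n_dropped=int(n_dropped),
        n_outside=n_outside,
        n_concordant=n_conc,
        permutation_p=float(p),
        n_perm=n_perm,
        seed=seed,
    )
    return (result, conc_null) if return_null else result


def write_expression_tsv(study: ExpressionStudy, matrix_path, samples_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_expression_tsv(matrix_path, samples_path,
                        floor: float = EXPRESSION_FLOOR) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return ExpressionStudy(matrix, samples, floor=floor)


def write_reference_tsv(reference_fc: pd.Series, path) -> None:
    reference_fc.rename("log2fc").to_csv(path, sep="\t", index_label="gene")


def read_reference_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if "log2fc" not in df.columns:
        raise ValueError("reference table needs a log2fc column")
    return df["log2fc"]
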