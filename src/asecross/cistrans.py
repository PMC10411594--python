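"""Cis/trans regulatory divergence classification.

Three tests feed a seven-way decision table, per sex x tissue x cross:

* **P** — differential expression between the two parental lines
  (NB likelihood-ratio test of the line effect on overall parental counts);
* **H** — allelic imbalance between the two alleles within hybrids
  (NB LRT of the allele effect, paired within sample by a sample covariate,
  reciprocal directions pooled as replicates);
* **T** — a trans effect: the allelic ratio differs between parents and
  hybrids (two-sided Fisher's exact test on the 2x2 table of summed counts
  [[P1, P2], [A1, A2]]).

With BH-FDR significance flags (sig_P, sig_H, sig_T) the categories are:
conserved (none), cis_only (P, H, not T), trans_only (P, T, not H),
compensatory (H, T, not P), cis_plus_trans / cis_by_trans (all three, split
on the ratio log2(P1/P2) / log2(A1/A2) >= 1 vs < 1 — same-allele vs
opposite-allele action of cis and trans), and ambiguous (exactly one flag).
The table is total over the eight flag combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AnalysisConfig,
    AseCountTable,
    Scope,
    obs_column,
    filter_parental_reads,
)
from .cr_glm import bh_adjust, estimate_dispersion, fitted_means, moderated_dispersions, nested_lrt

__all__ = [
    "TestTriple",
    "RegulatoryCall",
    "CATEGORIES",
    "test_parental_de",
    "test_hybrid_imbalance",
    "test_trans_fisher",
    "classify_regulatory",
    "run_cistrans",
]

CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "ambiguous",
)


@dataclass
class TestTriple:
    """The three per-gene test results underlying a regulatory call."""

    gene_id: str
    p_parental: float = np.nan
    p_hybrid: float = np.nan
    p_trans: float = np.nan
    fdr_parental: float = np.nan
    fdr_hybrid: float = np.nan
    fdr_trans: float = np.nan
    log2_parental: float = np.nan  # log2(P1/P2), pseudocounted
    log2_hybrid: float = np.nan  # log2(A1/A2), pseudocounted


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def test_parental_de(
    counts_p1: np.ndarray,
    counts_p2: np.ndarray,
    offsets_p1: np.ndarray,
    offsets_p2: np.ndarray,
    cfg: AnalysisConfig,
    dispersion: float | None = None,
) -> float:
    """NB LRT p-value for a line effect between the two parents.

    Counts are per-replicate overall counts; offsets are log library sizes.
    All-zero input returns p = 1 (no evidence either way).
    """
    y = np.concatenate([np.asarray(counts_p1, float), np.asarray(counts_p2, float)])
    if y.sum() == 0:
        return 1.0
    off = np.concatenate([np.asarray(offsets_p1, float), np.asarray(offsets_p2, float)])
    line = np.concatenate([np.zeros(len(counts_p1)), np.ones(len(counts_p2))])
    if y[line == 0].sum() == 0 or y[line == 1].sum() == 0:
        y = y + cfg.pseudocount
    const = np.ones(len(y))
    X_full = np.column_stack([const, line])
    X_red = const[:, None]
    min_obs = min(len(y), 4)
    if dispersion is None:
        dispersion = estimate_dispersion(y, X_full, off, min_obs=min_obs)
        if not np.isfinite(dispersion):
            return np.nan
    p, _, _, _ = nested_lrt(y, X_full, X_red, off, dispersion, min_obs=min_obs)
    return p


def test_hybrid_imbalance(
    allele_counts: pd.DataFrame,
    offsets: np.ndarray,
    cfg: AnalysisConfig,
    dispersion: float | None = None,
) -> float:
    """NB LRT p-value for allelic imbalance within hybrid samples.

    ``allele_counts`` is samples x 2 columns (A, B); the allele effect is
    tested against a model with per-sample intercepts, pairing the two
    alleles of each sample.  Missing samples simply shorten the design.
    """
    ac = allele_counts.to_numpy(dtype=float)
    n_s = ac.shape[0]
    y = ac.reshape(-1)  # sample-major: A, B per sample
    if y.sum() == 0:
        return 1.0
    allele = np.tile([0.0, 1.0], n_s)
    if y[allele == 0].sum() == 0 or y[allele == 1].sum() == 0:
        y = y + cfg.pseudocount
    off = np.repeat(np.asarray(offsets, float), 2)
    const = np.ones(2 * n_s)
    sample_dummies = np.repeat(np.eye(n_s)[:, 1:], 2, axis=0)
    X_red = np.column_stack([const, sample_dummies])
    X_full = np.column_stack([X_red, allele])
    min_obs = min(len(y), 4)
    if dispersion is None:
        dispersion = estimate_dispersion(y, X_full, off, min_obs=min_obs)
        if not np.isfinite(dispersion):
            return np.nan
    p, _, _, _ = nested_lrt(y, X_full, X_red, off, dispersion, min_obs=min_obs)
    return p


def test_trans_fisher(p1: float, p2: float, a1: float, a2: float) -> float:
    """Two-sided Fisher's exact p for a parent-vs-hybrid allelic-ratio shift.

    Inputs are summed estimated counts; they are rounded half-up to
    integers (the exact test requires integers).  An all-zero table gives
    p = 1.
    """
    table = _round_half_up(np.array([[p1, p2], [a1, a2]], dtype=float))
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table.astype(np.int64), alternative="two-sided")[1])


def classify_regulatory(
    sig_p: bool, sig_h: bool, sig_t: bool, log2_parental: float, log2_hybrid: float
) -> str:
    """Seven-way regulatory category from the three significance flags.

    The cis_plus_trans / cis_by_trans split uses
    ratio = log2(P1/P2) / log2(A1/A2); ratio >= 1 (same-allele action, with
    the parental divergence at least as large as the allelic one) is
    cis_plus_trans, ratio < 1 is cis_by_trans.  A ratio at exactly 1, and
    the degenerate log2_hybrid = 0 case, resolve to cis_plus_trans.
    """
    n_sig = int(sig_p) + int(sig_h) + int(sig_t)
    if n_sig == 0:
        return "conserved"
    if n_sig == 1:
        return "ambiguous"
    if sig_p and sig_h and not sig_t:
        return "cis_only"
    if sig_p and sig_t and not sig_h:
        return "trans_only"
    if sig_h and sig_t and not sig_p:
        return "compensatory"
    # all three significant
    if log2_hybrid == 0:
        return "cis_plus_trans"
    ratio = log2_parental / log2_hybrid
    return "cis_plus_trans" if ratio >= 1 else "cis_by_trans"


@dataclass
class RegulatoryCall:
    """Per-gene category with the underlying test triple."""

    gene_id: str
    category: str
    triple: TestTriple
    ratio: float = np.nan


def run_cistrans(
    parental_counts: pd.DataFrame,
    parental_meta: pd.DataFrame,
    hybrid: AseCountTable,
    cfg: AnalysisConfig,
    scope: Scope,
    pooled_reciprocals: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """The full classification for one sex x tissue x cross scope.

    Parental inputs are overall counts with a meta table carrying ``line``
    (P1/P2), ``sex``, ``tissue``, ``replicate``.  Hybrid allele counts come
    from the ASE table; reciprocal directions are pooled as replicates by
    default (set ``pooled_reciprocals=False`` to restrict to
    ``scope.direction``).  Returns (per-gene frame, category proportions).
    """
    pmask = pd.Series(True, index=parental_meta.index)
    for col, val in (("sex", scope.sex), ("tissue", scope.tissue)):
        if val is not None:
            pmask &= parental_meta[col] == val
    p1_samples = parental_meta.index[pmask & (parental_meta["line"] == "P1")].tolist()
    p2_samples = parental_meta.index[pmask & (parental_meta["line"] == "P2")].tolist()
    if not p1_samples or not p2_samples:
        raise ValueError("scope selects no parental samples for one of the lines")

    hyb_scope = scope if not pooled_reciprocals else Scope(
        sex=scope.sex, tissue=scope.tissue, cross_id=scope.cross_id
    )
    hyb_samples = hybrid.samples_in(hyb_scope)
    if not hyb_samples:
        raise ValueError("scope selects no hybrid samples")

    # eligibility: summed parental reads
    p_sums = pd.DataFrame(
        {
            "P1": parental_counts[p1_samples].sum(axis=1),
            "P2": parental_counts[p2_samples].sum(axis=1),
        }
    )
    genes = filter_parental_reads(p_sums, cfg).intersection(hybrid.autosomal_genes())

    p_lib = parental_counts[p1_samples + p2_samples].sum(axis=0)
    off_p1 = np.log(p_lib[p1_samples].to_numpy(dtype=float))
    off_p2 = np.log(p_lib[p2_samples].to_numpy(dtype=float))
    hyb_off = np.log(hybrid.meta.loc[hyb_samples, "library_size"].to_numpy(dtype=float))
    a_cols = [obs_column(s, "A") for s in hyb_samples]
    b_cols = [obs_column(s, "B") for s in hyb_samples]

    # pass 1: per-gene ML dispersions on each design, then empirical-Bayes
    # shrinkage toward the global trimmed mean (the moderation a dedicated
    # DE engine would apply; essential at 2-3 residual df)
    n1, n2, n_s = len(p1_samples), len(p2_samples), len(hyb_samples)
    line = np.concatenate([np.zeros(n1), np.ones(n2)])
    Xp = np.column_stack([np.ones(n1 + n2), line])
    off_p = np.concatenate([off_p1, off_p2])
    allele = np.tile([0.0, 1.0], n_s)
    Xh = np.column_stack(
        [np.ones(2 * n_s), np.repeat(np.eye(n_s)[:, 1:], 2, axis=0), allele]
    )
    off_h2 = np.repeat(hyb_off, 2)
    hybrid_ac: dict[str, pd.DataFrame] = {}
    yps, mups, ok_p = [], [], []
    yhs, muhs, ok_h = [], [], []
    for g in genes:
        yp = np.concatenate(
            [
                parental_counts.loc[g, p1_samples].to_numpy(dtype=float),
                parental_counts.loc[g, p2_samples].to_numpy(dtype=float),
            ]
        )
        if (yp == 0).any():
            yp = yp + cfg.pseudocount
        if yp.sum() > 0:
            mup = fitted_means(yp, Xp, off_p)
            if mup is not None:
                yps.append(yp)
                mups.append(mup)
                ok_p.append(g)
        ac = pd.DataFrame(
            {
                "A": hybrid.counts.loc[g, a_cols].to_numpy(dtype=float),
                "B": hybrid.counts.loc[g, b_cols].to_numpy(dtype=float),
            },
            index=hyb_samples,
        )
        hybrid_ac[g] = ac
        yh = ac.to_numpy(dtype=float).reshape(-1)
        if (yh == 0).any():
            yh = yh + cfg.pseudocount
        if yh.sum() > 0:
            muh = fitted_means(yh, Xh, off_h2)
            if muh is not None:
                yhs.append(yh)
                muhs.append(muh)
                ok_h.append(g)
    alphas_p, common_p = (
        moderated_dispersions(np.array(yps), np.array(mups), Xp, max(n1 + n2 - 2, 1),
                              cfg.dispersion_prior_df)
        if ok_p else (np.array([]), 0.1)
    )
    alphas_h, common_h = (
        moderated_dispersions(np.array(yhs), np.array(muhs), Xh, max(n_s - 1, 1),
                              cfg.dispersion_prior_df)
        if ok_h else (np.array([]), 0.1)
    )
    shrunk_p = pd.Series(alphas_p, index=pd.Index(ok_p)).reindex(genes).fillna(common_p)
    shrunk_h = pd.Series(alphas_h, index=pd.Index(ok_h)).reindex(genes).fillna(common_h)

    triples: list[TestTriple] = []
    for g in genes:
        t = TestTriple(gene_id=g)
        t.p_parental = test_parental_de(
            parental_counts.loc[g, p1_samples].to_numpy(dtype=float),
            parental_counts.loc[g, p2_samples].to_numpy(dtype=float),
            off_p1,
            off_p2,
            cfg,
            dispersion=float(shrunk_p[g]),
        )
        ac = hybrid_ac[g]
        t.p_hybrid = test_hybrid_imbalance(ac, hyb_off, cfg, dispersion=float(shrunk_h[g]))
        p1s, p2s = float(p_sums.loc[g, "P1"]), float(p_sums.loc[g, "P2"])
        a1s, a2s = float(ac["A"].sum()), float(ac["B"].sum())
        t.p_trans = test_trans_fisher(p1s, p2s, a1s, a2s)
        pc = cfg.pseudocount
        t.log2_parental = float(np.log2((p1s + pc) / (p2s + pc)))
        t.log2_hybrid = float(np.log2((a1s + pc) / (a2s + pc)))
        triples.append(t)

    frame = pd.DataFrame([t.__dict__ for t in triples]).set_index("gene_id")
    if frame.empty:
        return frame, pd.Series(0.0, index=list(CATEGORIES))
    frame["fdr_parental"] = bh_adjust(frame["p_parental"])
    frame["fdr_hybrid"] = bh_adjust(frame["p_hybrid"])
    frame["fdr_trans"] = bh_adjust(frame["p_trans"])

    cats = []
    ratios = []
    a = cfg.alpha_fdr
    for g, row in frame.iterrows():
        sig_p = bool(row["fdr_parental"] < a)
        sig_h = bool(row["fdr_hybrid"] < a)
        sig_t = bool(row["fdr_trans"] < a)
        cats.append(
            classify_regulatory(sig_p, sig_h, sig_t, row["log2_parental"], row["log2_hybrid"])
        )
        ratios.append(
            row["log2_parental"] / row["log2_hybrid"] if row["log2_hybrid"] != 0 else np.nan
        )
    frame["category"] = cats
    frame["ratio"] = ratios
    frame["scope"] = scope.label() + ("" if pooled_reciprocals else "_unpooled")

    proportions = (
        frame["category"].value_counts(normalize=True).reindex(CATEGORIES, fill_value=0.0)
    )
    return frame, proportions
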