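"""Inheritance-mode classification of hybrid expression.

A gene is eligible when its two parental means differ by at least a 1.5-fold
(and the summed parental reads pass the read filter).  Hybrid expression h
is then compared to the parental values lo = min(p1, p2), hi = max(p1, p2)
with a 1.25-fold cutoff f:

* overdominant:  h >= f * hi
* underdominant: h <= lo / f
* additive:      f * lo <= h <= hi / f   (above one parent, below the other)
* conserved:     within f of both parents (possible only for parental folds
  up to f^2)
* dominant:      within f of exactly one parent, >= f-fold from the other

Fold boundaries are inclusive by default (``cfg.inclusive_fold_bounds``);
over-/under-dominance take precedence, then additivity, then conservation,
then dominance, which makes the rule total and mutually exclusive on
eligible genes.  Expression values are floored at ``cfg.tpm_floor`` before
fold computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, Scope, filter_parental_reads
from .cr_glm import bh_adjust, estimate_dispersion, nested_lrt

__all__ = ["InheritanceCall", "MODES", "classify_inheritance", "run_inheritance"]

MODES = ("additive", "dominant", "overdominant", "underdominant", "conserved")


@dataclass
class InheritanceCall:
    gene_id: str
    mode: str  # one of MODES or "ineligible"
    eligible: bool
    which_parent_matched: str | None = None  # P1 | P2 for dominant calls


def classify_inheritance(
    p1: float,
    p2: float,
    h: float,
    cfg: AnalysisConfig,
    reads_ok: bool = True,
    gene_id: str = "",
) -> InheritanceCall:
    """Classify one gene from parental and hybrid expression values."""
    if p1 < 0 or p2 < 0 or h < 0:
        raise ValueError("expression values must be nonnegative")
    p1 = max(p1, cfg.tpm_floor)
    p2 = max(p2, cfg.tpm_floor)
    h = max(h, cfg.tpm_floor)
    f = cfg.hybrid_fold_cutoff

    def ge(a, b):  # "a at least b", boundary per config
        return a >= b if cfg.inclusive_fold_bounds else a > b

    def le(a, b):
        return a <= b if cfg.inclusive_fold_bounds else a < b

    lo, hi = min(p1, p2), max(p1, p2)
    eligible = reads_ok and ge(hi / lo, cfg.parental_fold_min)
    if not eligible:
        return InheritanceCall(gene_id, "ineligible", False)

    if ge(h, f * hi):
        return InheritanceCall(gene_id, "overdominant", True)
    if le(h, lo / f):
        return InheritanceCall(gene_id, "underdominant", True)
    if ge(h, f * lo) and le(h, hi / f):
        return InheritanceCall(gene_id, "additive", True)
    near_lo = le(h, f * lo) and ge(h, lo / f)
    near_hi = ge(h, hi / f) and le(h, f * hi)
    if near_lo and near_hi:
        return InheritanceCall(gene_id, "conserved", True)
    if near_hi:
        matched = "P1" if p1 >= p2 else "P2"
        return InheritanceCall(gene_id, "dominant", True, which_parent_matched=matched)
    # remaining region is adjacent to the low parent only
    matched = "P1" if p1 <= p2 else "P2"
    return InheritanceCall(gene_id, "dominant", True, which_parent_matched=matched)


def _classify_statistical(
    y_p1, y_p2, y_h, off_p1, off_p2, off_h, cfg: AnalysisConfig
) -> tuple[float, float]:
    """p-values for hybrid-vs-parent contrasts (NB LRT), one per parent."""
    out = []
    for y_p, off_p in ((y_p1, off_p1), (y_p2, off_p2)):
        y = np.concatenate([np.asarray(y_p, float), np.asarray(y_h, float)])
        off = np.concatenate([np.asarray(off_p, float), np.asarray(off_h, float)])
        grp = np.concatenate([np.zeros(len(y_p)), np.ones(len(y_h))])
        if y.sum() == 0:
            out.append(1.0)
            continue
        if y[grp == 0].sum() == 0 or y[grp == 1].sum() == 0:
            y = y + cfg.pseudocount
        const = np.ones(len(y))
        X_full = np.column_stack([const, grp])
        min_obs = min(len(y), 4)
        disp = estimate_dispersion(y, X_full, off, min_obs=min_obs)
        if not np.isfinite(disp):
            out.append(np.nan)
            continue
        p, _, _, _ = nested_lrt(y, X_full, const[:, None], off, disp, min_obs=min_obs)
        out.append(p)
    return out[0], out[1]


def run_inheritance(
    parental_tpm: pd.DataFrame,
    parental_meta: pd.DataFrame,
    hybrid_tpm: pd.DataFrame,
    hybrid_meta: pd.DataFrame,
    cfg: AnalysisConfig,
    scope: Scope,
    parental_counts: pd.DataFrame | None = None,
    method: str = "fold",
    hybrid_counts: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene inheritance calls and mode proportions for one scope.

    Parental TPM is averaged across replicates per line; hybrid TPM is
    averaged across reciprocal directions and replicates.  When
    ``parental_counts`` is given, the summed-read eligibility filter is
    applied on raw counts.  ``method="statistical"`` replaces the fold rules
    with NB-LRT hybrid-vs-parent contrasts at BH-FDR < ``cfg.alpha_fdr``
    (requires ``parental_counts`` and ``hybrid_counts``).
    """
    pmask = pd.Series(True, index=parental_meta.index)
    hmask = pd.Series(True, index=hybrid_meta.index)
    for col, val in (("sex", scope.sex), ("tissue", scope.tissue)):
        if val is not None:
            pmask &= parental_meta[col] == val
            hmask &= hybrid_meta[col] == val
    p1_s = parental_meta.index[pmask & (parental_meta["line"] == "P1")].tolist()
    p2_s = parental_meta.index[pmask & (parental_meta["line"] == "P2")].tolist()
    h_s = hybrid_meta.index[hmask].tolist()
    if not p1_s or not p2_s or not h_s:
        raise ValueError("scope selects no samples for at least one group")

    p1 = parental_tpm[p1_s].mean(axis=1)
    p2 = parental_tpm[p2_s].mean(axis=1)
    h = hybrid_tpm[h_s].mean(axis=1)
    genes = p1.index.intersection(h.index)

    reads_ok = pd.Series(True, index=genes)
    if parental_counts is not None:
        sums = pd.DataFrame(
            {
                "P1": parental_counts[p1_s].sum(axis=1),
                "P2": parental_counts[p2_s].sum(axis=1),
            }
        )
        passing = filter_parental_reads(sums, cfg)
        reads_ok = pd.Series(genes.isin(passing), index=genes)

    rows = []
    if method == "fold":
        for g in genes:
            call = classify_inheritance(
                float(p1[g]), float(p2[g]), float(h[g]), cfg,
                reads_ok=bool(reads_ok[g]), gene_id=g,
            )
            rows.append(call.__dict__)
        out = pd.DataFrame(rows).set_index("gene_id")
    elif method == "statistical":
        if parental_counts is None or hybrid_counts is None:
            raise ValueError("statistical method requires parental and hybrid counts")
        off_p1 = np.log(parental_counts[p1_s].sum(axis=0).to_numpy(dtype=float))
        off_p2 = np.log(parental_counts[p2_s].sum(axis=0).to_numpy(dtype=float))
        off_h = np.log(hybrid_counts[h_s].sum(axis=0).to_numpy(dtype=float))
        p_vs1, p_vs2 = [], []
        for g in genes:
            a, b = _classify_statistical(
                parental_counts.loc[g, p1_s].to_numpy(dtype=float),
                parental_counts.loc[g, p2_s].to_numpy(dtype=float),
                hybrid_counts.loc[g, h_s].to_numpy(dtype=float),
                off_p1, off_p2, off_h, cfg,
            )
            p_vs1.append(a)
            p_vs2.append(b)
        fdr1 = bh_adjust(p_vs1)
        fdr2 = bh_adjust(p_vs2)
        for i, g in enumerate(genes):
            elig = bool(reads_ok[g]) and (
                max(p1[g], p2[g]) / max(min(p1[g], p2[g]), cfg.tpm_floor)
                >= cfg.parental_fold_min
            )
            if not elig:
                rows.append(InheritanceCall(g, "ineligible", False).__dict__)
                continue
            d1 = fdr1[i] < cfg.alpha_fdr  # differs from P1
            d2 = fdr2[i] < cfg.alpha_fdr
            hv, lo, hi_ = float(h[g]), min(p1[g], p2[g]), max(p1[g], p2[g])
            if not d1 and not d2:
                call = InheritanceCall(g, "conserved", True)
            elif d1 != d2:
                matched = "P1" if d2 else "P2"
                call = InheritanceCall(g, "dominant", True, which_parent_matched=matched)
            elif hv > hi_:
                call = InheritanceCall(g, "overdominant", True)
            elif hv < lo:
                call = InheritanceCall(g, "underdominant", True)
            else:
                call = InheritanceCall(g, "additive", True)
            rows.append(call.__dict__)
        out = pd.DataFrame(rows).set_index("gene_id")
    else:
        raise ValueError(f"unknown method {method!r}")

    out["scope"] = scope.label()
    eligible = out[out["eligible"]]
    proportions = (
        eligible["mode"].value_counts(normalize=True).reindex(MODES, fill_value=0.0)
        if len(eligible)
        else pd.Series(0.0, index=list(MODES))
    )
    return out, proportions
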