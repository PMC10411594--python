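"""Per-gene negative-binomial GLMs for cis (CR), parent-of-origin (PO) and
maternal-genotype (MG) effects on allele-specific expression.

The base model per gene, within one sex x tissue x cross scope, is

    E ~ mu + CR + PO + MG + eps

on NB counts with a log link and log library-size offsets, where CR codes
the allele (A=0, B=1), PO the parental origin of the allele (maternal=0,
paternal=1) and MG the cross direction (AxB=0, BxA=1).  Each effect is
tested by a likelihood-ratio test of the full model against the model
dropping that term, with the NB dispersion estimated once on the full model
and held fixed across the nested fits, so nested deviance differences are
nonnegative by construction.  The deviance explained by CR — the drop in
deviance when CR is added to the PO+MG model — doubles as a per-gene effect
size.  Sex- and tissue-dependence of CR is assessed by a CR x factor
interaction model and by an explicit reversal model whose recoded CR column
(CRsex / CRtissue) is the allele code in one factor level and its complement
in the other, so it only aligns with opposite-direction allelic usage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, AseCountTable, ExpressionTable, Scope
from .core_io import build_design, filter_expressed

__all__ = [
    "NbFit",
    "CrGlmResult",
    "InteractionResult",
    "fit_nb",
    "nb_loglik",
    "estimate_dispersion",
    "test_cr_po_mg",
    "test_interaction",
    "test_reversal",
    "bh_adjust",
    "run_cr_glm",
    "run_interactions",
]

_ALPHA_MIN, _ALPHA_MAX = 1e-6, 50.0


@dataclass
class NbFit:
    """One negative-binomial GLM fit (log link, offsets)."""

    coefficients: np.ndarray
    deviance: float
    dispersion: float
    converged: bool
    n_obs: int
    loglik: float = np.nan
    skipped_reason: str | None = None

    @classmethod
    def skipped(cls, reason: str, n_obs: int = 0) -> "NbFit":
        return cls(
            coefficients=np.array([]),
            deviance=np.nan,
            dispersion=np.nan,
            converged=False,
            n_obs=n_obs,
            skipped_reason=reason,
        )


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (variance mu + alpha*mu^2); tolerates fractional y."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    if alpha < 1e-12:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    size = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + size)
            - special.gammaln(size)
            - special.gammaln(y + 1.0)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _ml_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile ML of the NB dispersion given fitted means."""
    res = optimize.minimize_scalar(
        lambda la: -nb_loglik(y, mu, np.exp(la)),
        bounds=(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def _glm_fit(y, X, offset, alpha, start_params=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
        return model.fit(start_params=start_params, maxiter=100, tol=1e-9)


def fit_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    dispersion: float | None = None,
    min_obs: int = 6,
) -> NbFit:
    """Maximum-likelihood NB GLM; profiles the dispersion when not supplied.

    Returns a skipped :class:`NbFit` (never raises) for insufficient or
    rank-deficient designs and for numerical failures.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    n = y.shape[0]
    if n < min_obs:
        return NbFit.skipped("insufficient design", n_obs=n)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return NbFit.skipped("rank-deficient design", n_obs=n)
    if X.shape[1] > n:
        return NbFit.skipped("insufficient design", n_obs=n)
    try:
        alpha = dispersion
        if alpha is None:
            alpha = 0.1  # starting value for the profile iteration
            res = None
            for _ in range(3):
                res = _glm_fit(y, X, offset, alpha)
                alpha = _ml_alpha(y, res.fittedvalues)
        res = _glm_fit(y, X, offset, alpha)
        return NbFit(
            coefficients=np.asarray(res.params, dtype=float),
            deviance=float(res.deviance),
            dispersion=float(alpha),
            converged=bool(getattr(res, "converged", True)),
            n_obs=n,
            loglik=nb_loglik(y, res.fittedvalues, alpha),
        )
    except Exception as exc:  # pragma: no cover - defensive
        return NbFit.skipped(f"fit failed: {exc.__class__.__name__}", n_obs=n)


def nested_lrt(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray,
    dispersion: float,
    min_obs: int = 6,
) -> tuple[float, float, NbFit, NbFit]:
    """LRT of a nested pair at fixed dispersion.

    Returns (p, delta_deviance, full_fit, reduced_fit); delta is clipped at
    zero after a restart of the full fit if the reduced model ever appears
    to fit better (a convergence artifact).
    """
    full = fit_nb(y, X_full, offset, dispersion=dispersion, min_obs=min_obs)
    red = fit_nb(y, X_reduced, offset, dispersion=dispersion, min_obs=min_obs)
    if full.skipped_reason or red.skipped_reason:
        return np.nan, np.nan, full, red
    delta = red.deviance - full.deviance
    if delta < 0:
        # restart the full fit from the reduced solution padded with zeros
        pad = np.zeros(X_full.shape[1])
        keep = _column_map(X_full, X_reduced)
        pad[keep] = red.coefficients
        try:
            res = _glm_fit(y, X_full, offset, dispersion, start_params=pad)
            if res.deviance < full.deviance:
                full = NbFit(
                    coefficients=np.asarray(res.params, dtype=float),
                    deviance=float(res.deviance),
                    dispersion=dispersion,
                    converged=True,
                    n_obs=full.n_obs,
                    loglik=nb_loglik(y, res.fittedvalues, dispersion),
                )
            delta = red.deviance - full.deviance
        except Exception:
            pass
        delta = max(delta, 0.0)
    df = X_full.shape[1] - X_reduced.shape[1]
    p = float(stats.chi2.sf(delta, df))
    return p, float(delta), full, red

def _column_map(X_full: np.ndarray, X_reduced: np.ndarray) -> list[int]:
    """Indices of full-model columns matching each reduced-model column."""
    idx = []
    for j in range(X_reduced.shape[1]):
        col = X_reduced[:, j]
        for k in range(X_full.shape[1]):
            if np.array_equal(X_full[:, k], col):
                idx.append(k)
                break
        else:  # pragma: no cover
            raise ValueError("reduced design is not nested in the full design")
    return idx


def estimate_dispersion(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, min_obs: int = 6
) -> float:
    """Per-gene profiled ML dispersion on the given (full) design."""
    fit = fit_nb(y, X, offset, dispersion=None, min_obs=min_obs)
    if fit.skipped_reason:
        return np.nan
    return float(np.clip(fit.dispersion, _ALPHA_MIN, _ALPHA_MAX))


_GRID = np.exp(np.linspace(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX), 72))


def _apl_curves(ys: np.ndarray, mus: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Genes x grid matrix of Cox-Reid adjusted NB profile log-likelihoods.

    The adjustment, -0.5 * logdet(X' W X) with the NB working weights
    W = mu / (1 + alpha * mu), removes the downward bias the fitted
    regression coefficients would otherwise impose on the dispersion.
    """
    ys = np.asarray(ys, dtype=float)
    mus = np.clip(np.asarray(mus, dtype=float), 1e-12, None)
    X = np.asarray(X, dtype=float)
    out = np.empty((ys.shape[0], _GRID.size))
    for j, a in enumerate(_GRID):
        size = 1.0 / a
        ll = np.sum(
            special.gammaln(ys + size)
            - special.gammaln(size)
            - special.gammaln(ys + 1.0)
            + size * np.log(size / (size + mus))
            + ys * np.log(mus / (size + mus)),
            axis=1,
        )
        w = mus / (1.0 + a * mus)
        info = np.einsum("gn,np,nq->gpq", w, X, X)
        _, logdet = np.linalg.slogdet(info)
        out[:, j] = ll - 0.5 * logdet
    return out


def _grid_argmax(curve: np.ndarray) -> float:
    """Alpha at the (quadratically refined) maximum of a grid curve."""
    j = int(np.argmax(curve))
    if j == 0 or j == _GRID.size - 1:
        return float(_GRID[j])
    x = np.log(_GRID[j - 1 : j + 2])
    y = curve[j - 1 : j + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom >= 0:
        return float(_GRID[j])
    shift = 0.5 * (y[0] - y[2]) / denom
    return float(np.exp(x[1] + shift * (x[1] - x[0])))


def moderated_dispersions(
    ys: np.ndarray,
    mus: np.ndarray,
    X: np.ndarray,
    residual_df: float,
    prior_df: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Weighted-likelihood dispersion moderation across genes.

    ``ys`` and ``mus`` are genes x observations arrays of counts and fitted
    means; ``X`` is the shared design.  The common dispersion maximizes the
    pooled Cox-Reid adjusted profile likelihood; each gene's dispersion
    maximizes its own adjusted likelihood plus ``prior_df / residual_df``
    times the genewise-average curve, shrinking noisy per-gene estimates
    toward the common value without boundary pathologies.  Returns
    (per-gene alphas, common alpha).
    """
    curves = _apl_curves(ys, mus, X)
    mean_curve = curves.mean(axis=0)
    common = _grid_argmax(mean_curve)
    weight = prior_df / max(residual_df, 1e-6)
    alphas = np.array([_grid_argmax(c + weight * mean_curve) for c in curves])
    return alphas, common


def fitted_means(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float = 0.1
) -> np.ndarray | None:
    """Fitted means from a single provisional-dispersion GLM fit."""
    try:
        res = _glm_fit(np.asarray(y, float), X, offset, alpha)
        return np.asarray(res.fittedvalues, dtype=float)
    except Exception:
        return None


@dataclass
class CrGlmResult:
    """Per-gene CR/PO/MG test results within one scope."""

    gene_id: str
    p_cr: float = np.nan
    p_po: float = np.nan
    p_mg: float = np.nan
    fdr_cr: float = np.nan
    fdr_po: float = np.nan
    fdr_mg: float = np.nan
    deviance_explained_cr: float = np.nan
    dispersion: float = np.nan
    n_obs: int = 0
    continuity_adjusted: bool = False
    skipped_reason: str | None = None


def _continuity_adjust(y: np.ndarray, cr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Half-count adjustment when one allele class is all zeros."""
    if y[cr == 0].sum() == 0 or y[cr == 1].sum() == 0:
        return y + 0.5, True
    return y, False


def test_cr_po_mg(
    y: np.ndarray,
    design: pd.DataFrame,
    cfg: AnalysisConfig,
    gene_id: str = "",
    dispersion: float | None = None,
) -> CrGlmResult:
    """Likelihood-ratio tests of CR, PO and MG for one gene.

    The dispersion is profiled on the full model (unless supplied) and held
    fixed across the three nested comparisons, making every deviance
    difference nonnegative.
    """
    y = np.asarray(y, dtype=float)
    cr = design["CR"].to_numpy(dtype=float)
    po = design["PO"].to_numpy(dtype=float)
    mg = design["MG"].to_numpy(dtype=float)
    offset = design["offset"].to_numpy(dtype=float)
    n = len(y)
    res = CrGlmResult(gene_id=gene_id, n_obs=n)
    if n < cfg.min_observations:
        res.skipped_reason = "insufficient design"
        return res
    if y.sum() == 0:
        res.skipped_reason = "all-zero counts"
        return res
    y, res.continuity_adjusted = _continuity_adjust(y, cr)

    const = np.ones(n)
    X_full = np.column_stack([const, cr, po, mg])
    if dispersion is None:
        dispersion = estimate_dispersion(y, X_full, offset, min_obs=cfg.min_observations)
        if not np.isfinite(dispersion):
            res.skipped_reason = "dispersion estimation failed"
            return res
    res.dispersion = float(dispersion)

    drops = {
        "cr": np.column_stack([const, po, mg]),
        "po": np.column_stack([const, cr, mg]),
        "mg": np.column_stack([const, cr, po]),
    }
    for name, X_red in drops.items():
        p, delta, full, red = nested_lrt(
            y, X_full, X_red, offset, dispersion, min_obs=cfg.min_observations
        )
        if not np.isfinite(p):
            res.skipped_reason = (full.skipped_reason or red.skipped_reason
                                  or "fit failed")
            return res
        setattr(res, f"p_{name}", p)
        if name == "cr":
            res.deviance_explained_cr = delta
    return res


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries (skipped genes) are passed through and excluded from m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def run_cr_glm(
    table: AseCountTable,
    allele_tpm: ExpressionTable,
    cfg: AnalysisConfig,
    scope: Scope,
) -> pd.DataFrame:
    """The full per-scope CR/PO/MG analysis.

    Filters genes on allele-level TPM, profiles per-gene dispersions on the
    full model, shrinks them toward the global trimmed mean (or replaces
    them by it under ``cfg.common_dispersion``), runs the fixed-dispersion
    LRTs, and applies BH correction per effect within the scope.
    """
    genes = filter_expressed(table, allele_tpm, cfg, scope)
    design = build_design(table, scope)
    counts = table.counts.loc[genes, design.index]
    cr = design["CR"].to_numpy(dtype=float)
    po = design["PO"].to_numpy(dtype=float)
    mg = design["MG"].to_numpy(dtype=float)
    offset = design["offset"].to_numpy(dtype=float)
    X_full = np.column_stack([np.ones(len(design)), cr, po, mg])

    ys, mus, ok_genes = [], [], []
    for g in genes:
        y, _ = _continuity_adjust(counts.loc[g].to_numpy(dtype=float), cr)
        if y.sum() == 0:
            continue
        mu = fitted_means(y, X_full, offset)
        if mu is None:
            continue
        ys.append(y)
        mus.append(mu)
        ok_genes.append(g)
    residual_df = max(len(design) - X_full.shape[1], 1)
    if ok_genes:
        alphas, common = moderated_dispersions(
            np.array(ys), np.array(mus), X_full, residual_df, cfg.dispersion_prior_df
        )
    else:
        alphas, common = np.array([]), 0.1
    if cfg.common_dispersion:
        shrunk = pd.Series(common, index=pd.Index(ok_genes))
    else:
        shrunk = pd.Series(alphas, index=pd.Index(ok_genes))
    shrunk = shrunk.reindex(genes).fillna(common)

    rows = []
    for g in genes:
        r = test_cr_po_mg(
            counts.loc[g].to_numpy(dtype=float), design, cfg, gene_id=g,
            dispersion=float(shrunk[g]),
        )
        rows.append(r.__dict__)
    out = pd.DataFrame(rows).set_index("gene_id")
    for eff in ("cr", "po", "mg"):
        out[f"fdr_{eff}"] = bh_adjust(out[f"p_{eff}"])
    out["scope"] = scope.label()
    return out


@dataclass
class InteractionResult:
    """CR x factor interaction or reversal test for one gene."""

    gene_id: str
    model: str  # sex_interaction | sex_reversal | tissue_interaction | tissue_reversal
    p: float = np.nan
    fdr: float = np.nan
    coefficient: float = np.nan
    n_obs: int = 0
    skipped_reason: str | None = None


_FACTOR_COL = {"sex": "sex_code", "tissue": "tissue_code"}


def test_interaction(
    y: np.ndarray,
    design: pd.DataFrame,
    factor: str,
    cfg: AnalysisConfig,
    gene_id: str = "",
    dispersion: float | None = None,
) -> InteractionResult:
    """LRT of the CR x factor term against the additive CR + factor model."""
    fac_col = _FACTOR_COL[factor]
    res = InteractionResult(gene_id=gene_id, model=f"{factor}_interaction", n_obs=len(y))
    y = np.asarray(y, dtype=float)
    cr = design["CR"].to_numpy(dtype=float)
    fac = design[fac_col].to_numpy(dtype=float)
    offset = design["offset"].to_numpy(dtype=float)
    if len(set(fac)) < 2 or any(
        len(set(cr[fac == lev])) < 2 for lev in np.unique(fac)
    ):
        res.skipped_reason = "factor level missing"
        return res
    y, _ = _continuity_adjust(y, cr)
    const = np.ones(len(y))
    X_full = np.column_stack([const, cr, fac, cr * fac])
    X_red = np.column_stack([const, cr, fac])
    if dispersion is None:
        dispersion = estimate_dispersion(y, X_full, offset, min_obs=cfg.min_observations)
        if not np.isfinite(dispersion):
            res.skipped_reason = "dispersion estimation failed"
            return res
    p, _, full, _ = nested_lrt(y, X_full, X_red, offset, dispersion,
                               min_obs=cfg.min_observations)
    if not np.isfinite(p):
        res.skipped_reason = full.skipped_reason or "fit failed"
        return res
    res.p = p
    res.coefficient = float(full.coefficients[3])
    return res


def test_reversal(
    y: np.ndarray,
    design: pd.DataFrame,
    factor: str,
    cfg: AnalysisConfig,
    gene_id: str = "",
    dispersion: float | None = None,
) -> InteractionResult:
    """LRT of the recoded CRsex/CRtissue model against the intercept.

    The recoded column equals CR in one factor level and 1-CR in the other,
    so it carries signal only when allelic usage points in opposite
    directions across levels.
    """
    fac_col = _FACTOR_COL[factor]
    res = InteractionResult(gene_id=gene_id, model=f"{factor}_reversal", n_obs=len(y))
    y = np.asarray(y, dtype=float)
    cr = design["CR"].to_numpy(dtype=float)
    fac = design[fac_col].to_numpy(dtype=float)
    offset = design["offset"].to_numpy(dtype=float)
    if len(set(fac)) < 2 or any(
        len(set(cr[fac == lev])) < 2 for lev in np.unique(fac)
    ):
        res.skipped_reason = "factor level missing"
        return res
    y, _ = _continuity_adjust(y, cr)
    cr_rev = np.where(fac == 0, cr, 1.0 - cr)
    const = np.ones(len(y))
    X_full = np.column_stack([const, cr_rev])
    X_red = const[:, None]
    if dispersion is None:
        dispersion = estimate_dispersion(y, X_full, offset, min_obs=cfg.min_observations)
        if not np.isfinite(dispersion):
            res.skipped_reason = "dispersion estimation failed"
            return res
    p, _, full, _ = nested_lrt(y, X_full, X_red, offset, dispersion,
                               min_obs=cfg.min_observations)
    if not np.isfinite(p):
        res.skipped_reason = full.skipped_reason or "fit failed"
        return res
    res.p = p
    res.coefficient = float(full.coefficients[1])
    return res


def run_interactions(
    table: AseCountTable,
    allele_tpm: ExpressionTable,
    cfg: AnalysisConfig,
    factor: str,
    scope: Scope,
) -> pd.DataFrame:
    """Interaction and reversal models for every gene in a two-level scope.

    For ``factor="sex"`` the scope fixes tissue (and cross) and spans both
    sexes; for ``factor="tissue"`` it fixes sex.  BH is applied per model
    within the scope.
    """
    genes = filter_expressed(table, allele_tpm, cfg, scope)
    design = build_design(table, scope)
    counts = table.counts.loc[genes, design.index]
    rows = []
    for g in genes:
        y = counts.loc[g].to_numpy(dtype=float)
        inter = test_interaction(y, design, factor, cfg, gene_id=g)
        rev = test_reversal(y, design, factor, cfg, gene_id=g)
        rows.append(inter.__dict__)
        rows.append(rev.__dict__)
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for model in out["model"].unique():
        m = out["model"] == model
        out.loc[m, "fdr"] = bh_adjust(out.loc[m, "p"])
    out["scope"] = scope.label()
    return out.set_index(["gene_id", "model"])
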