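"""Generative model for allele-specific counts in a reciprocal cross design.

Emulates one cross between two inbred lines (A, B): two reciprocal hybrid
directions x two replicates x two sexes x two tissues, plus parental
samples, with negative-binomial counts around gene-level expected means
carrying known cis, trans, parent-of-origin (PO), maternal-genotype (MG)
and inheritance-mode structure.  Every effect is recorded per gene in
:class:`GeneTruth` so recovery and calibration of each inference stage can
be measured against ground truth.

Generative model (per gene, per sex/tissue context, unscaled means):

* parent 1:            ``b``
* parent 2:            ``b * 2**(cis + trans)``
* hybrid allele A:     ``b * 2**(trans/2) * 2**(po*[A paternal]) * 2**(mg*[BxA])``
* hybrid allele B:     the same times ``2**cis``

where ``b = base_mean * 2**(+-sb/2)`` (plus for females).  The hybrid trans
environment is the geometric midpoint of the two parental backgrounds, so a
pure-trans gene diverges between parents while keeping balanced hybrid
alleles — exactly the signature the cis/trans classifier keys on.  When a
target depth is configured, per-sample means over all genes are scaled so
the expected total matches it; counts are NB with variance
``mu + dispersion * mu**2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AseCountTable, ExpressionTable, parent_of_origin

EFFECT_CLASSES = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "po",
    "mg",
    "sex_reversed",
)

INHERITANCE_MODES = (
    "additive",
    "dominant_p1",
    "dominant_p2",
    "overdominant",
    "underdominant",
)

#: regulatory classes whose parents diverge, hence can carry a non-conserved
#: inheritance mode (compensatory parents coincide by construction)
_DIVERGENT_CLASSES = ("cis_only", "trans_only", "cis_plus_trans", "cis_by_trans")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Effect-class fractions are applied by exact (largest-remainder)
    allocation, the remainder being null genes.  Effect sizes are drawn as
    ``sign * |Normal(mean, sd)|`` per gene; base means and dispersions are
    log-normal around their stated medians.  ``depth``, when set, rescales
    every sample so its expected library size matches it; when ``None``
    (default) expected counts stay on the base_mean scale and the library
    size is whatever the gene content implies.  The default dispersion of
    0.01 (BCV 10%) reflects replicate pools of many genetically identical
    individuals.
    """

    n_genes: int = 2000
    n_replicates: int = 2
    depth: float | None = None
    prop_cis_only: float = 0.10
    prop_trans_only: float = 0.10
    prop_cis_plus_trans: float = 0.05
    prop_cis_by_trans: float = 0.05
    prop_compensatory: float = 0.05
    prop_po: float = 0.02
    prop_mg: float = 0.02
    prop_sex_reversed: float = 0.02
    cis_log2fc: float = 1.0
    trans_log2fc: float = 1.0
    po_log2fc: float = 1.0
    mg_log2fc: float = 1.0
    log2fc_sd: float = 0.25
    base_mean: float = 200.0
    base_mean_log_sd: float = 1.0
    dispersion: float = 0.01
    dispersion_log_sd: float = 0.5
    sb_sd: float = 1.0
    sexes: tuple[str, ...] = ("F", "M")
    tissues: tuple[str, ...] = ("head", "gonad")
    cross_id: str = "cross1"
    drop_samples: tuple[str, ...] = ()
    seed: int = 0

    def class_proportions(self) -> dict[str, float]:
        return {c: getattr(self, f"prop_{c}") for c in EFFECT_CLASSES}

    def __post_init__(self) -> None:
        total = sum(self.class_proportions().values())
        if total > 1.0 + 1e-12:
            raise ValueError(f"effect-class proportions sum to {total} > 1")
        if any(p < 0 for p in self.class_proportions().values()):
            raise ValueError("effect-class proportions must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class GeneTruth:
    """Ground-truth generative parameters for one gene."""

    gene_id: str
    class_label: str  # "null" or one of EFFECT_CLASSES
    base_mean: float
    cis_log2fc: dict[tuple[str, str], float]  # keyed by (sex, tissue)
    trans_log2fc: dict[tuple[str, str], float]
    po_log2fc: float
    mg_log2fc: float
    inheritance_mode: str  # "conserved" or one of INHERITANCE_MODES
    dispersion: float
    sb_true: float

    def __post_init__(self) -> None:
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")


def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion n items to classes exactly (Hamilton / largest remainder)."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:short]] += 1
    return counts.tolist()


def simulate_truth(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[GeneTruth]:
    """Draw per-gene ground truth; deterministic given the config seed."""
    rng = rng or np.random.default_rng(cfg.seed)
    props = cfg.class_proportions()
    alloc = largest_remainder(cfg.n_genes, list(props.values()) + [1.0 - sum(props.values())])
    labels: list[str] = []
    for cls, k in zip(list(props) + ["null"], alloc):
        labels.extend([cls] * k)

    contexts = [(s, t) for s in cfg.sexes for t in cfg.tissues]
    width = len(str(cfg.n_genes))
    truths: list[GeneTruth] = []
    divergent_counter = 0
    for i, label in enumerate(labels):
        base = cfg.base_mean * float(np.exp(rng.normal(0.0, cfg.base_mean_log_sd))) \
            if cfg.base_mean_log_sd > 0 else cfg.base_mean
        disp = cfg.dispersion * float(np.exp(rng.normal(0.0, cfg.dispersion_log_sd))) \
            if cfg.dispersion_log_sd > 0 else cfg.dispersion
        sb = float(rng.normal(0.0, cfg.sb_sd)) if cfg.sb_sd > 0 else 0.0

        sign = float(rng.choice([-1.0, 1.0]))
        mag = lambda mean: abs(float(rng.normal(mean, cfg.log2fc_sd)))  # noqa: E731

        cis = {c: 0.0 for c in contexts}
        trans = {c: 0.0 for c in contexts}
        po = 0.0
        mg = 0.0
        if label == "cis_only":
            v = sign * mag(cfg.cis_log2fc)
            cis = {c: v for c in contexts}
        elif label == "trans_only":
            v = sign * mag(cfg.trans_log2fc)
            trans = {c: v for c in contexts}
        elif label == "cis_plus_trans":
            cv, tv = sign * mag(cfg.cis_log2fc), sign * mag(cfg.trans_log2fc)
            cis = {c: cv for c in contexts}
            trans = {c: tv for c in contexts}
        elif label == "cis_by_trans":
            cv, tv = sign * mag(cfg.cis_log2fc), -sign * mag(cfg.trans_log2fc)
            cis = {c: cv for c in contexts}
            trans = {c: tv for c in contexts}
        elif label == "compensatory":
            cv = sign * mag(cfg.cis_log2fc)
            cis = {c: cv for c in contexts}
            trans = {c: -cv for c in contexts}
        elif label == "po":
            po = sign * mag(cfg.po_log2fc)
        elif label == "mg":
            mg = sign * mag(cfg.mg_log2fc)
        elif label == "sex_reversed":
            v = mag(cfg.cis_log2fc)
            cis = {(s, t): (v if s == "F" else -v) for (s, t) in contexts}

        if label in _DIVERGENT_CLASSES:
            mode = INHERITANCE_MODES[divergent_counter % len(INHERITANCE_MODES)]
            divergent_counter += 1
        else:
            mode = "conserved"

        truths.append(
            GeneTruth(
                gene_id=f"g{i + 1:0{width}d}",
                class_label=label,
                base_mean=base,
                cis_log2fc=cis,
                trans_log2fc=trans,
                po_log2fc=po,
                mg_log2fc=mg,
                inheritance_mode=mode,
                dispersion=disp,
                sb_true=sb,
            )
        )
    return truths


def expected_means(
    truth: GeneTruth,
    sex: str,
    tissue: str,
    role: str,
    direction: str | None = None,
) -> tuple[float, float]:
    """Unscaled expected (allele A, allele B) means for one sample context.

    Roles: ``parent1`` (all expression on allele A), ``parent2`` (allele B),
    ``hybrid`` (requires a direction).  Values are proportional only;
    per-sample depth scaling happens in :func:`simulate_counts`.
    """
    key = (sex, tissue)
    if key not in truth.cis_log2fc:
        raise ValueError(f"unknown context {key!r}")
    sexfac = 2.0 ** (truth.sb_true / 2.0) if sex == "F" else 2.0 ** (-truth.sb_true / 2.0)
    b = truth.base_mean * sexfac
    cis = truth.cis_log2fc[key]
    trans = truth.trans_log2fc[key]
    if role == "parent1":
        return b, 0.0
    if role == "parent2":
        return 0.0, b * 2.0 ** (cis + trans)
    if role == "hybrid":
        if direction is None:
            raise ValueError("hybrid context requires a direction")
        mgf = 2.0 ** truth.mg_log2fc if direction == "BxA" else 1.0
        shared = b * 2.0 ** (trans / 2.0) * mgf
        po_a = truth.po_log2fc if parent_of_origin(direction, "A") == "paternal" else 0.0
        po_b = truth.po_log2fc if parent_of_origin(direction, "B") == "paternal" else 0.0
        return shared * 2.0 ** po_a, shared * 2.0 ** cis * 2.0 ** po_b
    raise ValueError(f"unknown role {role!r}")


def _overall_hybrid_mean(truth: GeneTruth, sex: str, tissue: str, direction: str) -> float:
    """Overall (allele-summed, TPM-scale) hybrid mean implied by the
    inheritance mode, before depth scaling.  MG multiplies the whole sample
    for the BxA direction; PO cancels in the allele sum by design of the
    overall layer."""
    p1, _ = expected_means(truth, sex, tissue, "parent1")
    _, p2 = expected_means(truth, sex, tissue, "parent2")
    mode = truth.inheritance_mode
    if mode == "additive":
        h = 0.5 * (p1 + p2)
    elif mode == "dominant_p1":
        h = p1
    elif mode == "dominant_p2":
        h = p2
    elif mode == "overdominant":
        h = 1.5 * max(p1, p2)
    elif mode == "underdominant":
        h = min(p1, p2) / 1.5
    else:  # conserved: parents coincide (ratio 1) for these classes
        h = 0.5 * (p1 + p2)
    if direction == "BxA":
        h *= 2.0 ** truth.mg_log2fc
    return h


@dataclass
class SimulatedData:
    """All simulator outputs for one reciprocal cross."""

    cfg: SimConfig
    truths: list[GeneTruth]
    hybrid_ase: AseCountTable
    hybrid_allele_tpm: ExpressionTable
    parental_counts: pd.DataFrame  # genes x parental samples
    parental_meta: pd.DataFrame  # line, sex, tissue, replicate per sample
    parental_tpm: ExpressionTable
    hybrid_overall_counts: pd.DataFrame  # genes x hybrid samples (allele-summed layer)
    hybrid_overall_meta: pd.DataFrame
    hybrid_overall_tpm: ExpressionTable

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = {
                "gene_id": t.gene_id,
                "class_label": t.class_label,
                "base_mean": t.base_mean,
                "po_log2fc": t.po_log2fc,
                "mg_log2fc": t.mg_log2fc,
                "inheritance_mode": t.inheritance_mode,
                "dispersion": t.dispersion,
                "sb_true": t.sb_true,
            }
            for (s, ti), v in t.cis_log2fc.items():
                row[f"cis_log2fc_{s}_{ti}"] = v
            for (s, ti), v in t.trans_log2fc.items():
                row[f"trans_log2fc_{s}_{ti}"] = v
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB draws with variance mu + disp*mu^2; Poisson in the disp -> 0 limit."""
    mu = np.asarray(mu, dtype=float)
    disp = np.broadcast_to(np.asarray(disp, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=float)
    tiny = disp < 1e-9
    out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        size = 1.0 / disp[~tiny]
        p = size / (size + mu[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out


def expected_mean_matrix(truths: list[GeneTruth], cfg: SimConfig) -> pd.DataFrame:
    """Depth-scaled expected hybrid allele means, one column per observation.

    The closed-form oracle for the count layer: simulated counts are NB draws
    around exactly these values.
    """
    genes = [t.gene_id for t in truths]
    cols: dict[str, np.ndarray] = {}
    for sex in cfg.sexes:
        for tissue in cfg.tissues:
            for direction in ("AxB", "BxA"):
                means = np.array(
                    [expected_means(t, sex, tissue, "hybrid", direction) for t in truths]
                )  # genes x 2
                scale = 1.0 if cfg.depth is None else cfg.depth / means.sum()
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{cfg.cross_id}_{direction}_{sex}_{tissue}_R{rep}"
                    if sid in cfg.drop_samples:
                        continue
                    cols[f"{sid}.A"] = means[:, 0] * scale
                    cols[f"{sid}.B"] = means[:, 1] * scale
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def simulate_counts(
    truths: list[GeneTruth], cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimulatedData:
    """Draw the full set of count and TPM tables around the expected means."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    genes = pd.Index([t.gene_id for t in truths], name="gene_id")
    disp = np.array([t.dispersion for t in truths])

    # hybrid allele-specific layer
    mu = expected_mean_matrix(truths, cfg)
    counts = pd.DataFrame(
        {c: _nb_draw(rng, mu[c].to_numpy(), disp) for c in mu.columns}, index=genes
    )
    meta_rows = []
    for sex in cfg.sexes:
        for tissue in cfg.tissues:
            for direction in ("AxB", "BxA"):
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{cfg.cross_id}_{direction}_{sex}_{tissue}_R{rep}"
                    if sid in cfg.drop_samples:
                        continue
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "cross_id": cfg.cross_id,
                            "direction": direction,
                            "sex": sex,
                            "tissue": tissue,
                            "replicate": rep,
                            "library_size": 0.0,
                        }
                    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    hybrid_ase = AseCountTable(counts=counts, meta=meta)
    allele_tpm = ExpressionTable(
        counts / counts.sum(axis=0).replace(0.0, np.nan) * 1e6, role="allele_tpm"
    )
    allele_tpm.values.fillna(0.0, inplace=True)

    # parental overall layer (2 replicates per line per sex x tissue)
    p_cols: dict[str, np.ndarray] = {}
    p_meta = []
    for sex in cfg.sexes:
        for tissue in cfg.tissues:
            p1 = np.array([expected_means(t, sex, tissue, "parent1")[0] for t in truths])
            p2 = np.array([expected_means(t, sex, tissue, "parent2")[1] for t in truths])
            for line, vec in (("P1", p1), ("P2", p2)):
                scale = 1.0 if cfg.depth is None else cfg.depth / vec.sum()
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{cfg.cross_id}_{line}_{sex}_{tissue}_R{rep}"
                    if sid in cfg.drop_samples:
                        continue
                    p_cols[sid] = _nb_draw(rng, vec * scale, disp)
                    p_meta.append(
                        {"sample_id": sid, "line": line, "sex": sex, "tissue": tissue,
                         "replicate": rep}
                    )
    parental_counts = pd.DataFrame(p_cols, index=genes)
    parental_meta = pd.DataFrame(p_meta).set_index("sample_id")
    parental_tpm = ExpressionTable(
        parental_counts / parental_counts.sum(axis=0) * 1e6, role="parental_overall"
    )

    # hybrid overall layer (inheritance-mode means, allele-agnostic)
    h_cols: dict[str, np.ndarray] = {}
    h_meta = []
    for sex in cfg.sexes:
        for tissue in cfg.tissues:
            for direction in ("AxB", "BxA"):
                vec = np.array(
                    [_overall_hybrid_mean(t, sex, tissue, direction) for t in truths]
                )
                scale = 1.0 if cfg.depth is None else cfg.depth / vec.sum()
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{cfg.cross_id}_H{direction}_{sex}_{tissue}_R{rep}"
                    if sid in cfg.drop_samples:
                        continue
                    h_cols[sid] = _nb_draw(rng, vec * scale, disp)
                    h_meta.append(
                        {"sample_id": sid, "direction": direction, "sex": sex,
                         "tissue": tissue, "replicate": rep}
                    )
    hybrid_overall_counts = pd.DataFrame(h_cols, index=genes)
    hybrid_overall_meta = pd.DataFrame(h_meta).set_index("sample_id")
    hybrid_overall_tpm = ExpressionTable(
        hybrid_overall_counts / hybrid_overall_counts.sum(axis=0) * 1e6,
        role="hybrid_overall",
    )

    return SimulatedData(
        cfg=cfg,
        truths=truths,
        hybrid_ase=hybrid_ase,
        hybrid_allele_tpm=allele_tpm,
        parental_counts=parental_counts,
        parental_meta=parental_meta,
        parental_tpm=parental_tpm,
        hybrid_overall_counts=hybrid_overall_counts,
        hybrid_overall_meta=hybrid_overall_meta,
        hybrid_overall_tpm=hybrid_overall_tpm,
    )


def simulate(cfg: SimConfig) -> SimulatedData:
    """Convenience wrapper: truth then counts, both driven by cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    truths = simulate_truth(cfg, rng)
    return simulate_counts(truths, cfg, rng)
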