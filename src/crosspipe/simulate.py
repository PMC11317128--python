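"""Synthetic-data generators with known ground truth.

Bulk counts follow a negative-binomial model with variance
``mu + dispersion * mu^2``, log-normal library-size factors, group-wise
fold changes on chosen genes and an optional stratum of lowly expressed
genes (baseline mean near 1) emulating the noise floor the expression
filter targets. Cell-level counts add per-cell-type marker over-expression
so the pseudobulk + marker-truth benchmark closes the loop. Every generator
threads an explicit integer seed; identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ContrastSpec, CountMatrix, GeneSetCollection, SampleSheet
from .errors import ValidationError

__all__ = [
    "SimTruth",
    "simulate_bulk_counts",
    "simulate_cell_counts",
    "make_toy_collections",
    "scenario_low_signal",
    "scenario_benchmark1",
    "scenario_benchmark3",
]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    de_genes: dict = field(default_factory=dict)
    planted_sets: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    perturbed_group: str | None = None
    dispersion: float = 0.0
    low_count_fraction: float = 0.0
    low_count_genes: list = field(default_factory=list)
    seed: int = 0


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)


def simulate_bulk_counts(
    n_genes: int,
    groups: dict[str, int],
    baseline_mu: float = 200.0,
    dispersion: float = 0.2,
    lfc_map: dict[str, float] | None = None,
    libsize_cv: float = 0.3,
    low_count_fraction: float = 0.3,
    seed: int = 0,
    perturbed_group: str | None = None,
) -> tuple[CountMatrix, SampleSheet, SimTruth]:
    """Negative-binomial bulk counts with group structure.

    Per-gene baseline means are log-normal around ``baseline_mu`` except for
    a ``low_count_fraction`` stratum drawn near 1. Genes in ``lfc_map``
    (gene id -> log2 fold change) have their mean multiplied by
    ``2**lfc`` in the ``perturbed_group`` (default: alphabetically first
    group, the numerator of lexicographic contrasts). Gene ids are
    ``g0001...``; sample ids ``<group>_<i>``.
    """
    if n_genes < 1 or baseline_mu <= 0 or dispersion < 0:
        raise ValidationError("invalid simulation parameters")
    if not 0.0 <= low_count_fraction <= 1.0:
        raise ValidationError("low_count_fraction must lie in [0, 1]")
    if len(groups) < 1 or any(n < 1 for n in groups.values()):
        raise ValidationError("each group needs at least one sample")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    lfc_map = dict(lfc_map or {})
    unknown = set(lfc_map) - set(gene_ids)
    if unknown:
        raise ValidationError(f"lfc_map refers to unknown genes: {sorted(unknown)[:5]}")
    group_names = sorted(groups)
    if perturbed_group is None:
        perturbed_group = group_names[0]
    if perturbed_group not in groups:
        raise ValidationError(f"perturbed group {perturbed_group!r} not in groups")

    n_low = int(round(low_count_fraction * n_genes))
    low_idx = rng.choice(n_genes, size=n_low, replace=False)
    mu0 = np.exp(rng.normal(np.log(baseline_mu), 1.0, size=n_genes))
    mu0[low_idx] = np.exp(rng.normal(0.0, 0.5, size=n_low))  # near 1

    lfc = np.zeros(n_genes)
    pos = {g: i for i, g in enumerate(gene_ids)}
    for g, value in lfc_map.items():
        lfc[pos[g]] = value

    sample_ids: list[str] = []
    sample_groups: list[str] = []
    columns = []
    for group in group_names:
        for i in range(groups[group]):
            sample_ids.append(f"{group}_{i + 1}")
            sample_groups.append(group)
    lib_factors = _lognormal_factors(rng, len(sample_ids), libsize_cv)
    for j, group in enumerate(sample_groups):
        mu = mu0 * lib_factors[j]
        if group == perturbed_group:
            mu = mu * np.exp2(lfc)
        columns.append(_nb_sample(rng, mu, dispersion))

    counts = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=sample_ids
    )
    sheet = SampleSheet(pd.DataFrame({"sample_id": sample_ids, "group": sample_groups}))
    truth = SimTruth(
        de_genes=lfc_map,
        groups=dict(groups),
        perturbed_group=perturbed_group,
        dispersion=dispersion,
        low_count_fraction=low_count_fraction,
        low_count_genes=[gene_ids[i] for i in sorted(low_idx)],
        seed=seed,
    )
    return CountMatrix(counts), sheet, truth


def simulate_cell_counts(
    cell_types: list[str],
    markers_per_type: int = 20,
    cells_per_sample: int | dict = 30,
    samples: int = 3,
    n_background_genes: int = 300,
    marker_fold: float = 8.0,
    depth: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection]:
    """Cell-level counts where each cell type over-expresses its own markers.

    ``cells_per_sample`` may be an int or a mapping cell_type -> cell count
    (useful to plant under-populated pseudobulks). Returns (cells x genes
    counts, per-cell metadata with ``sample`` and ``cell_type`` columns, and
    the matching marker :class:`GeneSetCollection` named
    ``celltype_markers`` so the marker-truth benchmark closes the loop).
    """
    if len(cell_types) < 2:
        raise ValidationError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    marker_ids = {
        ct: [f"mk_{ct}_{i + 1:03d}" for i in range(markers_per_type)]
        for ct in cell_types
    }
    background = [f"bg{i + 1:04d}" for i in range(n_background_genes)]
    genes = background + [g for ct in cell_types for g in marker_ids[ct]]
    base_mu = np.exp(rng.normal(np.log(depth), 0.8, size=len(genes)))

    marker_pos = {
        ct: [len(background) + i + j * markers_per_type for i in range(markers_per_type)]
        for j, ct in enumerate(cell_types)
    }

    rows, cell_ids, meta_rows = [], [], []
    for s in range(samples):
        sample = f"s{s + 1}"
        for ct in cell_types:
            n_cells = cells_per_sample[ct] if isinstance(cells_per_sample, dict) else cells_per_sample
            for c in range(n_cells):
                mu = base_mu.copy()
                mu[marker_pos[ct]] *= marker_fold
                mu *= rng.lognormal(0.0, 0.2)  # per-cell depth variation
                rows.append(rng.poisson(mu))
                cell_ids.append(f"{sample}_{ct}_{c + 1}")
                meta_rows.append((sample, ct))
    counts = pd.DataFrame(np.vstack(rows), index=cell_ids, columns=genes)
    meta = pd.DataFrame(meta_rows, index=cell_ids, columns=["sample", "cell_type"])
    markers = GeneSetCollection(
        "celltype_markers", {ct: [(g, 1.0) for g in marker_ids[ct]] for ct in cell_types}
    )
    return counts, meta, markers


def make_toy_collections(
    seed: int = 0, n_genes: int = 2000
) -> tuple[GeneSetCollection, GeneSetCollection, GeneSetCollection]:
    """Three desk-scale collections mimicking the common resource shapes.

    * ``pathway_toy`` — 14 pathway-like sets (responsive-gene style),
    * ``hallmark_toy`` — 50 hallmark-like independent sets,
    * ``tf_toy`` — 30 TF-like signed regulons (weights +1 activation / -1
      repression).

    Gene ids follow the ``g0001...`` universe of
    :func:`simulate_bulk_counts`; every set has at least 5 genes.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i + 1:04d}" for i in range(n_genes)])

    def _draw(n_sets: int, prefix: str, size_lo: int, size_hi: int, signed: bool):
        sets = {}
        for k in range(n_sets):
            size = int(rng.integers(size_lo, size_hi + 1))
            members = rng.choice(genes, size=size, replace=False)
            if signed:
                weights = rng.choice([1.0, -1.0], size=size, p=[0.8, 0.2])
            else:
                weights = np.ones(size)
            sets[f"{prefix}{k + 1:02d}"] = list(zip(members.tolist(), weights.tolist()))
        return sets

    pathway = GeneSetCollection("pathway_toy", _draw(14, "PW", 25, 60, signed=False))
    hallmark = GeneSetCollection("hallmark_toy", _draw(50, "HM", 20, 50, signed=False))
    tf = GeneSetCollection("tf_toy", _draw(30, "TF", 10, 40, signed=True))
    return pathway, hallmark, tf


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def scenario_low_signal(
    seed: int = 0,
    n_contrasts: int = 30,
    n_genes: int = 1200,
    n_per_group: int = 4,
    lfc: float = 0.5,
    low_count_fraction: float = 0.4,
    dispersion: float = 0.3,
) -> dict:
    """Low-signal decoupling scenario: many weak contrasts, heavy noise floor.

    Each contrast is an independent two-group dataset (n vs n) with a small
    planted fold change (|lfc| = 0.5 by default) on the genes of one
    hallmark-like set, plus a 40% low-count stratum. Returns a dict with
    ``datasets`` (list of (CountMatrix, SampleSheet, ContrastSpec, SimTruth))
    and ``collections``.
    """
    rng = np.random.default_rng(seed)
    pathway, hallmark, tf = make_toy_collections(seed=seed, n_genes=n_genes)
    datasets = []
    set_ids = hallmark.set_ids
    for k in range(n_contrasts):
        target = set_ids[int(rng.integers(len(set_ids)))]
        lfc_map = {g: lfc for g, _ in hallmark.sets[target]}
        m, s, truth = simulate_bulk_counts(
            n_genes=n_genes,
            groups={"A": n_per_group, "B": n_per_group},
            dispersion=dispersion,
            lfc_map=lfc_map,
            low_count_fraction=low_count_fraction,
            seed=int(rng.integers(2 ** 31)),
        )
        truth.planted_sets = {target: lfc}
        datasets.append((m, s, ContrastSpec("A", "B", f"c{k + 1:02d}"), truth))
    return {"datasets": datasets, "collections": [pathway, hallmark, tf]}


def scenario_benchmark1(
    seed: int = 0,
    n_datasets: int = 2,
    cell_types: list[str] | None = None,
    samples: int = 3,
) -> dict:
    """Marker-recovery scenario: cell-level data for pseudobulk benchmarks.

    Simulates ``n_datasets`` independent single-cell studies over 7 cell
    types; one-vs-rest contrasts against the matching marker collection give
    1 positive among 7 candidates per contrast.
    """
    if cell_types is None:
        cell_types = ["CM", "Endo", "Fib", "Lymphoid", "Myeloid", "PC", "vSMC"]
    rng = np.random.default_rng(seed)
    studies = []
    markers = None
    for d in range(n_datasets):
        counts, meta, markers = simulate_cell_counts(
            cell_types, samples=samples, seed=int(rng.integers(2 ** 31))
        )
        studies.append((f"study{d + 1}", counts, meta))
    return {"studies": studies, "markers": markers, "cell_types": cell_types}


def scenario_benchmark3(
    seed: int = 0,
    n_contrasts: int = 18,
    n_genes: int = 1200,
    n_per_group: int = 3,
    signal_fraction: float = 0.6,
    lfc: float = 1.2,
    baseline_mu: float = 5.0,
    low_count_fraction: float = 0.7,
    dispersion: float = 0.6,
) -> dict:
    """Perturbation-recovery scenario with moderate, partly absent signal.

    Each contrast maps to one hallmark-like set; in ``signal_fraction`` of
    contrasts the mapped set's genes carry a planted fold change, the rest
    are null (non-responsive contexts). The defaults emulate shallow
    pseudobulk-style profiles: low sequencing depth, a heavy near-zero
    stratum and strong overdispersion, so that most of the transcriptome
    sits at the detection floor and unfiltered pipelines must cope with its
    noise. Returns datasets, the hallmark-like collection and the
    perturbation -> gene-set mapping tables for the truth builder.
    """
    rng = np.random.default_rng(seed)
    _, hallmark, _ = make_toy_collections(seed=seed, n_genes=n_genes)
    candidates = hallmark.set_ids[:6]  # small mapped universe, 1/6 prevalence
    datasets, mapping_rows, contrast_rows = [], [], []
    for k in range(n_contrasts):
        target = candidates[int(rng.integers(len(candidates)))]
        responsive = rng.random() < signal_fraction
        lfc_map = (
            {g: lfc for g, _ in hallmark.sets[target]} if responsive else {}
        )
        m, s, truth = simulate_bulk_counts(
            n_genes=n_genes,
            groups={"treated": n_per_group, "vehicle": n_per_group},
            baseline_mu=baseline_mu,
            dispersion=dispersion,
            lfc_map=lfc_map,
            low_count_fraction=low_count_fraction,
            seed=int(rng.integers(2 ** 31)),
            perturbed_group="treated",
        )
        cid = f"pert{k + 1:02d}"
        truth.planted_sets = {target: lfc if responsive else 0.0}
        datasets.append(
            (m, s, ContrastSpec("treated", "vehicle", cid), truth)
        )
        mapping_rows.append((cid, target))
        contrast_rows.append((cid, cid))
    mapping = pd.DataFrame(mapping_rows, columns=["perturbation", "gene_set"])
    # the full candidate universe must appear in the mapping table
    mapping = pd.concat(
        [mapping, pd.DataFrame({"perturbation": ["_universe"] * len(candidates),
                                "gene_set": candidates})],
        ignore_index=True,
    ).drop_duplicates()
    contrast_perturbations = pd.DataFrame(
        contrast_rows, columns=["contrast", "perturbation"]
    )
    return {
        "datasets": datasets,
        "hallmark": hallmark,
        "mapping": mapping,
        "contrast_perturbations": contrast_perturbations,
        "candidates": candidates,
    }
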