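"""Synthetic 16S amplicon communities with known ground truth.

Emulates what amplicon classification of agricultural-soil samples
yields: count tables over thousands of taxa with a log-normal abundance
distribution (a few dominant groups, a heavy rare tail), a sizeable
fraction of reads in "unspecific" catch-all labels at the lowest ranks, a
small non-bacterial admixture, and paired control/treatment samples that
share a base community on which a treatment applies fold-changes to
selected taxa.

Sampling model: each sample's composition is the base (control) or
perturbed (treated) proportion vector, optionally jittered by a
Dirichlet draw with concentration ``overdispersion * proportions``
(site-to-site variability); reads are then drawn multinomially at a fixed
depth. With ``overdispersion = inf`` (the default) there is no site
noise, so a no-effect treated sample is exchangeable with its control —
the null condition under which the downstream paired screen holds its
nominal error rate.

All randomness flows from a single integer seed per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, EmptySelectionError
from .tables import RANKS, UNSPECIFIC_LABELS, TaxonCountTable

__all__ = [
    "TaxonomyTable",
    "GroundTruth",
    "Experiment",
    "generate_taxonomy",
    "draw_abundances",
    "perturb_abundances",
    "pick_specific_taxon",
    "set_proportion",
    "sample_experiment",
]

#: Average number of children spawned per parent at each rank below kingdom
#: (phylum..genus); species labels are unique per taxon. Tuned to give
#: realistic group counts (tens of phyla, hundreds of families, ~n_taxa/3
#: genera) for communities of a few thousand taxa.
_BRANCHING = {"phylum": 40, "class": 2, "order": 2, "family": 2, "genus": 3}


@dataclass
class TaxonomyTable:
    """Lineages over the seven ranks for a set of taxa.

    ``lineages`` is indexed by taxon_id with one column per rank;
    ``domain_label`` (Bacteria/Archaea/Eukaryota) equals the kingdom
    label. ``unspecific_flags`` marks, per rank, labels drawn from the
    unspecific vocabulary ("environmental samples", "unclassified",
    "No hits", "Not assigned").
    """

    lineages: pd.DataFrame

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.lineages.index)

    @property
    def n_taxa(self) -> int:
        return len(self.lineages)

    @property
    def domain_label(self) -> pd.Series:
        return self.lineages["kingdom"]

    @property
    def unspecific_flags(self) -> pd.DataFrame:
        return self.lineages.isin(UNSPECIFIC_LABELS)


def generate_taxonomy(
    n_taxa: int,
    unclassified_fraction: float = 0.3,
    seed: int = 0,
    archaea_fraction: float = 0.01,
    eukaryota_fraction: float = 0.02,
) -> TaxonomyTable:
    """Random, internally consistent lineages for ``n_taxa`` taxa.

    ``round(n_taxa * unclassified_fraction)`` taxa carry unspecific
    labels at the genus and species ranks (catch-all groups dominate at
    the lowest ranks). Small fractions of lineages are rooted in Archaea
    or Eukaryota instead of Bacteria. Labels embed their ancestor path,
    so equal lineage prefixes always denote equal ancestors.
    Deterministic given the seed.
    """
    if n_taxa < 1:
        raise EmptySelectionError("n_taxa must be >= 1")
    for name, frac in (
        ("unclassified_fraction", unclassified_fraction),
        ("archaea_fraction", archaea_fraction),
        ("eukaryota_fraction", eukaryota_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise DomainError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_arch = int(round(n_taxa * archaea_fraction))
    n_euk = int(round(n_taxa * eukaryota_fraction))
    kingdoms = np.array(
        ["Archaea"] * n_arch + ["Eukaryota"] * n_euk + ["Bacteria"] * (n_taxa - n_arch - n_euk)
    )
    rng.shuffle(kingdoms)

    # Draw a path of child indices per taxon; the label at each rank joins
    # the parent's index path, which guarantees lineage consistency.
    rows = []
    for i in range(n_taxa):
        path = []
        for rank in RANKS[1:-1]:  # phylum..genus
            path.append(int(rng.integers(_BRANCHING[rank])))
        prefix = kingdoms[i][:3].lower()
        lineage = [kingdoms[i]]
        for depth, rank in enumerate(RANKS[1:-1], start=1):
            code = ".".join(str(c) for c in path[:depth])
            lineage.append(f"{prefix}_{rank[0]}{code}")
        lineage.append(f"{prefix}_sp{i}")
        rows.append(lineage)

    lin = pd.DataFrame(
        rows,
        columns=list(RANKS),
        index=pd.Index([f"tax{i:05d}" for i in range(n_taxa)], name="taxon_id"),
    )

    n_unspec = int(round(n_taxa * unclassified_fraction))
    unspec_idx = rng.permutation(n_taxa)[:n_unspec]
    labels = sorted(UNSPECIFIC_LABELS)
    for i in unspec_idx:
        lin.iloc[i, lin.columns.get_loc("genus")] = labels[rng.integers(len(labels))]
        lin.iloc[i, lin.columns.get_loc("species")] = labels[rng.integers(len(labels))]
    return TaxonomyTable(lineages=lin)


def draw_abundances(n_taxa: int, lognormal_sigma: float = 2.0, seed: int = 0) -> np.ndarray:
    """Log-normal relative abundances: exp(N(0, sigma^2)) normalised to 1.

    sigma = 0 degenerates to the uniform community; sigma around 2 gives
    the uneven profile typical of soil (most taxa below the mean share).
    """
    if n_taxa < 1:
        raise EmptySelectionError("n_taxa must be >= 1")
    if lognormal_sigma < 0:
        raise DomainError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, lognormal_sigma, size=n_taxa))
    return raw / raw.sum()


def perturb_abundances(base: np.ndarray, effects: dict[int, float]) -> np.ndarray:
    """Apply fold-changes to selected taxa and renormalise to sum 1.

    ``effects`` maps taxon index -> fold-change (>= 0; 1 is identity, 0
    annihilates the taxon).
    """
    p = np.asarray(base, dtype=float)
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise DomainError("base must be a proportion vector summing to 1")
    out = p.copy()
    for idx, fold in effects.items():
        if fold < 0:
            raise DomainError(f"fold-change for taxon {idx} is negative")
        out[idx] = out[idx] * fold
    total = out.sum()
    if total <= 0:
        raise DomainError("effects annihilated the entire community")
    return out / total


def pick_specific_taxon(
    taxonomy: TaxonomyTable, base: np.ndarray, target_proportion: float
) -> int:
    """Index of the clearly-identified bacterial taxon whose base abundance
    is closest to ``target_proportion``.

    Useful for placing treatment effects on taxa that survive the
    unspecific-group filter (effects on catch-all-labelled taxa are
    invisible to the downstream screen by design).
    """
    flags = taxonomy.unspecific_flags.any(axis=1).to_numpy()
    bacterial = (taxonomy.domain_label == "Bacteria").to_numpy()
    ok = bacterial & ~flags
    if not ok.any():
        raise EmptySelectionError("no clearly-identified bacterial taxon available")
    idx = np.flatnonzero(ok)
    return int(idx[np.argmin(np.abs(np.asarray(base)[idx] - target_proportion))])


def set_proportion(base: np.ndarray, index: int, proportion: float) -> np.ndarray:
    """Pin one taxon to an exact relative abundance, rescaling the rest.

    Returns a new proportion vector with ``base[index] = proportion`` and
    the remaining mass distributed proportionally to the original values.
    """
    if not 0.0 < proportion < 1.0:
        raise DomainError("proportion must be in (0, 1)")
    p = np.asarray(base, dtype=float).copy()
    rest = p.sum() - p[index]
    if rest <= 0:
        raise DomainError("cannot rescale: no mass outside the pinned taxon")
    p[index] = 0.0
    p *= (1.0 - proportion) / rest
    p[index] = proportion
    return p / p.sum()


@dataclass
class GroundTruth:
    """The unobserved true community an experiment samples from."""

    base_proportions: np.ndarray
    effects: dict[int, float] = field(default_factory=dict)
    overdispersion: float = math.inf  # Dirichlet concentration; inf = no site noise
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.base_proportions, dtype=float)
        if np.any(p < 0):
            raise DomainError("proportions must be non-negative")
        if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise DomainError("proportions must sum to 1 (tolerance 1e-9)")
        if any(f < 0 for f in self.effects.values()):
            raise DomainError("fold-changes must be >= 0")
        if self.overdispersion <= 0:
            raise DomainError("overdispersion must be positive (inf disables noise)")
        self.base_proportions = p

    @property
    def treated_proportions(self) -> np.ndarray:
        return perturb_abundances(self.base_proportions, self.effects)


@dataclass
class Experiment:
    """A simulated paired experiment: counts, pairing manifest, truth."""

    table: TaxonCountTable
    manifest: pd.DataFrame  # pair_id, treated_sample, control_sample, treatment_code, time
    truth: GroundTruth
    taxonomy: TaxonomyTable


def _site_composition(
    rng: np.random.Generator, center: np.ndarray, overdispersion: float
) -> np.ndarray:
    if math.isinf(overdispersion):
        return center
    comp = np.zeros_like(center)
    pos = center > 0  # Dirichlet is only defined on the positive support
    comp[pos] = rng.dirichlet(overdispersion * center[pos])
    return comp


def sample_experiment(
    truth: GroundTruth,
    taxonomy: TaxonomyTable,
    depth_per_sample: int = 10_000,
    n_pairs: int = 1,
    seed: int | None = None,
    treatment_code: str = "AT",
    time: str = "t1",
) -> Experiment:
    """Draw a paired control/treatment experiment from the ground truth.

    For each pair a control composition (centred on the base proportions)
    and a treated composition (centred on the fold-change-perturbed
    proportions) are drawn — Dirichlet-jittered when ``overdispersion``
    is finite — and reads are sampled multinomially at
    ``depth_per_sample``, so every sample's counts sum exactly to the
    requested depth. Deterministic given the seed (default:
    ``truth.seed``).
    """
    if depth_per_sample < 1:
        raise DomainError("depth_per_sample must be >= 1")
    if n_pairs < 1:
        raise DomainError("n_pairs must be >= 1")
    if taxonomy.n_taxa != truth.base_proportions.size:
        raise DomainError("taxonomy and ground truth disagree on the number of taxa")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    treated_p = truth.treated_proportions
    columns: dict[str, np.ndarray] = {}
    manifest_rows = []
    for k in range(1, n_pairs + 1):
        t_name, c_name = f"pair{k:02d}_T", f"pair{k:02d}_C"
        comp_c = _site_composition(rng, truth.base_proportions, truth.overdispersion)
        comp_t = _site_composition(rng, treated_p, truth.overdispersion)
        columns[t_name] = rng.multinomial(depth_per_sample, comp_t)
        columns[c_name] = rng.multinomial(depth_per_sample, comp_c)
        manifest_rows.append(
            {
                "pair_id": f"pair{k:02d}",
                "treated_sample": t_name,
                "control_sample": c_name,
                "treatment_code": treatment_code,
                "time": time,
            }
        )

    lineages = [tuple(row) for row in taxonomy.lineages.itertuples(index=False)]
    counts = np.column_stack([columns[name] for name in columns])
    table = TaxonCountTable.from_lineages(
        lineages, counts, samples=list(columns), level="species"
    )
    return Experiment(
        table=table,
        manifest=pd.DataFrame(manifest_rows),
        truth=truth,
        taxonomy=taxonomy,
    )
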