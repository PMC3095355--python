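"""Synthetic EST-study generator with known ground truth.

Emulates the statistical structure of a transcript-derived duplication
study: codon sequence pairs diverged to a prescribed Ks under the same GY94
model class the estimator fits, duplication ages drawn from an exponential +
normals mixture truncated to the analysis window, power-law family sizes,
multinomial per-library EST count profiles with controllable co-regulation
between paralogs, and gene families evolved along random ultrametric
duplication trees so that every pairwise Ks and every node age is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import UNIFORM_POSITION_FREQS, SENSE_CODONS, f3x4_codon_frequencies
from .ks import CodonModel
from .pairs import CodingGene

__all__ = [
    "MixtureTruth",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_codon_pair",
    "simulate_age_sample",
    "simulate_family_sizes",
    "simulate_expression",
    "simulate_dataset",
    "DEFAULT_TISSUE_CLASSES",
]

DEFAULT_TISSUE_CLASSES = ("fruit", "vegetative", "reproductive", "vascular")


@dataclass(frozen=True)
class MixtureTruth:
    """True duplication-age mixture: exponential decay of small-scale
    duplications plus 0-3 normal bursts of large-scale events.

    Weights (exponential + normals) must be non-negative and sum to one.
    Defaults are the fitted values of the reference apple analysis: death
    rate 1.892, a young polyploidy peak at Ks 0.185 (sd 0.08) and an old
    triplication peak at Ks 1.65 (variance 0.31).
    """

    death_rate: float = 1.892
    w_exp: float = 0.45
    components: tuple = ((0.185, 0.08**2, 0.35), (1.65, 0.31, 0.20))

    def __post_init__(self):
        if self.death_rate <= 0:
            raise ValueError("death_rate must be positive")
        weights = [self.w_exp] + [w for _, _, w in self.components]
        if any(w < 0 for w in weights):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {sum(weights)}")
        if any(var <= 0 for _, var, _ in self.components):
            raise ValueError("normal component variances must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a full synthetic dataset.

    The same seed always yields a byte-identical dataset.
    """

    seed: int
    n_families: int = 200
    mixture_truth: MixtureTruth = field(default_factory=MixtureTruth)
    powerlaw_exponent: float = 2.35
    min_family_size: int = 2
    max_family_size: int = 250
    n_libraries: int = 14
    library_sizes: tuple | int = 2000
    tissue_map: tuple | None = None
    n_codons: int = 200
    kappa: float = 2.0
    omega: float = 0.2
    upper_ks: float = 2.0
    coregulated_fraction: float = 0.18
    tissue_shift_fraction: float = 0.25
    singleton_fraction: float = 0.31

    def __post_init__(self):
        if self.n_families < 1:
            raise ValueError("n_families must be at least 1")
        if self.powerlaw_exponent <= 1:
            raise ValueError("powerlaw_exponent must exceed 1")
        if not 0 <= self.coregulated_fraction <= 1:
            raise ValueError("coregulated_fraction must be in [0, 1]")
        if self.tissue_map is not None and len(self.tissue_map) != self.n_libraries:
            raise ValueError("tissue_map must assign every library")

    def resolved_library_sizes(self) -> np.ndarray:
        if np.isscalar(self.library_sizes):
            return np.full(self.n_libraries, int(self.library_sizes))
        sizes = np.asarray(self.library_sizes, dtype=int)
        if sizes.shape != (self.n_libraries,):
            raise ValueError("library_sizes length must equal n_libraries")
        return sizes

    def resolved_tissue_map(self) -> tuple:
        """Library -> tissue class; default spreads 4 classes over libraries."""
        if self.tissue_map is not None:
            return tuple(self.tissue_map)
        classes = DEFAULT_TISSUE_CLASSES
        return tuple(classes[i % len(classes)] for i in range(self.n_libraries))


@dataclass
class SimulatedDataset:
    """Full synthetic dataset plus the truth needed for recovery tests."""

    genes: list
    true_pair_ks: dict
    true_family_ids: dict
    true_coregulation: dict
    counts: pd.DataFrame
    tissue_map: dict
    config: SimulationConfig

    @property
    def gene_ids(self):
        return [g.id for g in self.genes]


# ---------------------------------------------------------------------------
# codon pair simulation
# ---------------------------------------------------------------------------

def _evolve(codon_idx: np.ndarray, P: np.ndarray, rng: np.random.Generator):
    """One categorical transition per site, grouped by source codon."""
    out = np.empty_like(codon_idx)
    for c in np.unique(codon_idx):
        mask = codon_idx == c
        out[mask] = rng.choice(len(SENSE_CODONS), size=int(mask.sum()), p=P[c])
    return out


def divergence_for_ks(ks_target: float, model: CodonModel) -> float:
    """Divergence t (subst/codon) whose model-expected Ks is ``ks_target``.

    Under the flux decomposition Ks is linear in t, so
    ``t = ks_target * 3 * rho_syn(omega=1) / rho_syn``.
    """
    rho1 = CodonModel(model.pi, model.kappa, 1.0).rho_syn
    return ks_target * 3.0 * rho1 / model.rho_syn


def simulate_codon_pair(n_codons: int, ks_target: float, kappa: float = 2.0,
                        omega: float = 0.2, seed: int | None = None,
                        position_freqs: np.ndarray | None = None):
    """Two stop-free CDS diverged so the model-expected Ks is ``ks_target``.

    An ancestral codon sequence is drawn from F3x4 equilibrium frequencies
    (uniform position profile unless supplied) and the two descendants evolve
    independently for t/2 each by exact matrix-exponential transition
    sampling under the GY94 rate matrix.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be at least 10")
    if ks_target < 0:
        raise ValueError("ks_target must be non-negative")
    rng = np.random.default_rng(seed)
    if position_freqs is None:
        position_freqs = UNIFORM_POSITION_FREQS
    pi = f3x4_codon_frequencies(position_freqs)
    model = CodonModel(pi, kappa, omega)
    ancestor = rng.choice(len(SENSE_CODONS), size=n_codons, p=model.pi)
    if ks_target == 0:
        a = b = ancestor
    else:
        t = divergence_for_ks(ks_target, model)
        P_half = model.transition_matrix(t / 2.0)
        a = _evolve(ancestor, P_half, rng)
        b = _evolve(ancestor, P_half, rng)
    to_cds = lambda idx: "".join(SENSE_CODONS[i] for i in idx)
    return to_cds(a), to_cds(b)


# ---------------------------------------------------------------------------
# duplication ages
# ---------------------------------------------------------------------------

def simulate_age_sample(n: int, truth: MixtureTruth, upper: float = 2.0,
                        seed: int | None = None, return_labels: bool = False):
    """i.i.d. draws from the age mixture, rejection-truncated to (0, upper].

    Component labels (0 = exponential, 1.. = normals) are retained for
    diagnostics when ``return_labels`` is set.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if upper <= 0:
        raise ValueError("upper must be positive")
    rng = np.random.default_rng(seed)
    weights = np.array([truth.w_exp] + [w for _, _, w in truth.components])
    ages = np.empty(n)
    labels = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        todo = n - filled
        comp = rng.choice(len(weights), size=todo, p=weights)
        draw = np.empty(todo)
        exp_mask = comp == 0
        draw[exp_mask] = rng.exponential(1.0 / truth.death_rate, int(exp_mask.sum()))
        for k, (mu, var, _) in enumerate(truth.components, start=1):
            mask = comp == k
            draw[mask] = rng.normal(mu, np.sqrt(var), int(mask.sum()))
        keep = (draw > 0) & (draw <= upper)
        kept = int(keep.sum())
        ages[filled : filled + kept] = draw[keep]
        labels[filled : filled + kept] = comp[keep]
        filled += kept
    if return_labels:
        return ages, labels
    return ages


# ---------------------------------------------------------------------------
# family sizes
# ---------------------------------------------------------------------------

def simulate_family_sizes(n_families: int, exponent: float, min_size: int = 2,
                          max_size: int = 250, seed: int | None = None):
    """Family sizes from a discrete power law P(x) ~ x^-exponent on a range."""
    if n_families < 1:
        raise ValueError("n_families must be at least 1")
    if exponent <= 1:
        raise ValueError("exponent must exceed 1")
    if not 2 <= min_size <= max_size:
        raise ValueError("need 2 <= min_size <= max_size")
    rng = np.random.default_rng(seed)
    support = np.arange(min_size, max_size + 1)
    pmf = support.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(support, size=n_families, p=pmf)


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

def _disjoint_profiles(n_libraries, tissue_classes, rng, concentration):
    """Two profiles with complementary tissue-class support."""
    classes = sorted(set(tissue_classes))
    split = rng.permutation(len(classes))
    half = max(1, len(classes) // 2)
    set_a = {classes[i] for i in split[:half]}
    prof_a = np.zeros(n_libraries)
    prof_b = np.zeros(n_libraries)
    for lib in range(n_libraries):
        if tissue_classes[lib] in set_a:
            prof_a[lib] = rng.gamma(concentration) + 1e-12
        else:
            prof_b[lib] = rng.gamma(concentration) + 1e-12
    return prof_a / prof_a.sum(), prof_b / prof_b.sum()


def simulate_expression(genes, n_libraries: int, library_sizes,
                        coregulated_fraction: float, seed: int | None = None,
                        pairs=None, tissue_map=None,
                        tissue_shift_fraction: float = 0.25,
                        concentration: float = 0.3):
    """EST count matrix with planted co-regulation structure.

    Each gene carries a latent expression profile over libraries (a Dirichlet
    draw; small concentration gives realistic tissue-biased EST profiles).
    For each paralog pair a status is planted: ``coregulated`` pairs share
    one profile, ``tissue-shifted`` pairs get complementary tissue-class
    supports, and the remaining ``divergent`` pairs draw independent
    profiles.  Counts are one multinomial draw per library across genes.

    Returns ``(counts, truth)`` with counts a genes x libraries DataFrame and
    truth a mapping pair -> status.
    """
    gene_ids = [g.id if isinstance(g, CodingGene) else str(g) for g in genes]
    rng = np.random.default_rng(seed)
    if np.isscalar(library_sizes):
        library_sizes = np.full(n_libraries, int(library_sizes))
    library_sizes = np.asarray(library_sizes, dtype=int)
    if tissue_map is None:
        tissue_map = tuple(
            DEFAULT_TISSUE_CLASSES[i % len(DEFAULT_TISSUE_CLASSES)]
            for i in range(n_libraries)
        )
    pairs = [tuple(p) for p in (pairs or [])]

    profiles: dict[str, np.ndarray] = {}
    truth: dict[tuple, str] = {}

    def fresh_profile():
        return rng.dirichlet(np.full(n_libraries, concentration))

    for a, b in pairs:
        u = rng.random()
        if u < coregulated_fraction:
            status = "coregulated"
        elif u < coregulated_fraction + (1 - coregulated_fraction) * tissue_shift_fraction:
            status = "tissue-shifted"
        else:
            status = "divergent"
        if a in profiles and b in profiles:
            # both already constrained by earlier pairs: record what holds
            same = np.allclose(profiles[a], profiles[b])
            disjoint = not np.any((profiles[a] > 0) & (profiles[b] > 0))
            status = "coregulated" if same else (
                "tissue-shifted" if disjoint else "divergent")
        elif status == "coregulated":
            base = profiles.get(a, profiles.get(b))
            if base is None:
                base = fresh_profile()
            profiles[a] = base
            profiles[b] = base
        elif status == "tissue-shifted":
            pa, pb = _disjoint_profiles(n_libraries, tissue_map, rng, concentration)
            if a in profiles:
                profiles[b] = pb if np.any(profiles[a] > 0) else pa
            else:
                profiles[a] = pa
                profiles[b] = pb
        else:
            profiles.setdefault(a, fresh_profile())
            profiles.setdefault(b, fresh_profile())
        truth[(a, b)] = status

    for g in gene_ids:
        profiles.setdefault(g, fresh_profile())

    prof = np.vstack([profiles[g] for g in gene_ids])  # genes x libraries
    counts = np.zeros((len(gene_ids), n_libraries), dtype=int)
    for lib in range(n_libraries):
        w = prof[:, lib]
        total = w.sum()
        if total <= 0:
            continue
        counts[:, lib] = rng.multinomial(library_sizes[lib], w / total)
    frame = pd.DataFrame(
        counts, index=gene_ids,
        columns=[f"lib{i + 1:02d}" for i in range(n_libraries)],
    )
    return frame, truth


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def _random_ultrametric(ages_sorted, rng):
    """Random ultrametric topology: merge random cluster pairs at the given
    ascending node ages.  Returns (n_leaves, merges) where each merge is
    (left_members, right_members, age)."""
    k = len(ages_sorted) + 1
    clusters = [[i] for i in range(k)]
    merges = []
    for age in ages_sorted:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        right = clusters.pop(j)
        left = clusters.pop(i)
        merges.append((left, right, float(age)))
        clusters.append(left + right)
    return k, merges


def _evolve_family(k, merges, model, t_per_ks, n_codons, rng):
    """Evolve codon sequences down a family's duplication tree.

    Node heights are half the pairwise Ks of the lineages they join, so two
    leaves whose most recent common duplication sits at age a accumulate a/2
    of Ks each and show pairwise Ks = a.  Returns leaf index -> codon-index
    array.
    """
    ancestor = rng.choice(len(SENSE_CODONS), size=n_codons, p=model.pi)
    if not merges:
        return {0: ancestor}

    def branch(seq_idx, dks):
        if dks <= 0:
            return seq_idx.copy()
        P = model.transition_matrix(dks * t_per_ks)
        return _evolve(seq_idx, P, rng)

    heights = {frozenset(l) | frozenset(r): age / 2.0 for l, r, age in merges}
    children = {frozenset(l) | frozenset(r): (frozenset(l), frozenset(r))
                for l, r, _ in merges}
    root = frozenset(range(k))
    seqs = {root: ancestor}
    leaves: dict[int, np.ndarray] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        h_node = heights.get(node, 0.0)
        for child in children.get(node, ()):
            h_child = heights.get(child, 0.0)
            seqs[child] = branch(seqs[node], h_node - h_child)
            if len(child) > 1:
                stack.append(child)
            else:
                (leaf,) = child
                leaves[leaf] = seqs[child]
    return leaves


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset per a SimulationConfig.

    Families get power-law sizes; each family's n-1 duplication ages are
    mixture draws arranged on a random ultrametric tree; sequences evolve
    along the tree under GY94 so that true pairwise Ks equals the age of the
    joining node; singletons are unrelated random sequences; EST counts are
    planted with the configured co-regulation structure.
    """
    rng = np.random.default_rng(config.seed)
    pi = f3x4_codon_frequencies(UNIFORM_POSITION_FREQS)
    model = CodonModel(pi, config.kappa, config.omega)
    t_per_ks = divergence_for_ks(1.0, model)

    sizes = simulate_family_sizes(
        config.n_families, config.powerlaw_exponent, config.min_family_size,
        config.max_family_size, seed=rng.integers(2**31),
    )
    genes: list[CodingGene] = []
    true_pair_ks: dict[tuple, float] = {}
    true_family_ids: dict[str, str] = {}
    all_pairs: list[tuple] = []

    for f, size in enumerate(sizes):
        fam_id = f"F{f + 1:04d}"
        ages = np.sort(simulate_age_sample(
            size - 1, config.mixture_truth, upper=config.upper_ks,
            seed=rng.integers(2**31),
        ))
        k, merges = _random_ultrametric(ages, rng)
        leaves = _evolve_family(k, merges, model, t_per_ks, config.n_codons, rng)
        ids = {leaf: f"{fam_id}_g{leaf + 1}" for leaf in range(k)}
        for leaf in range(k):
            cds = "".join(SENSE_CODONS[i] for i in leaves[leaf])
            genes.append(CodingGene(id=ids[leaf], cds=cds))
            true_family_ids[ids[leaf]] = fam_id
        # pairwise Ks = age of the node joining the two leaves
        for left, right, age in merges:
            for la in left:
                for lb in right:
                    key = tuple(sorted((ids[la], ids[lb])))
                    true_pair_ks[key] = age
                    all_pairs.append(key)

    n_family_genes = len(genes)
    n_singletons = int(round(
        config.singleton_fraction / (1 - config.singleton_fraction) * n_family_genes
    ))
    for s in range(n_singletons):
        idx = rng.choice(len(SENSE_CODONS), size=config.n_codons, p=model.pi)
        cds = "".join(SENSE_CODONS[i] for i in idx)
        genes.append(CodingGene(id=f"S{s + 1:04d}", cds=cds))

    tissue_classes = config.resolved_tissue_map()
    counts, truth_coreg = simulate_expression(
        genes, config.n_libraries, config.resolved_library_sizes(),
        config.coregulated_fraction, seed=rng.integers(2**31),
        pairs=all_pairs, tissue_map=tissue_classes,
        tissue_shift_fraction=config.tissue_shift_fraction,
    )
    for gene in genes:
        gene.est_counts = counts.loc[gene.id].to_numpy()
    tissue_map = {f"lib{i + 1:02d}": tissue_classes[i]
                  for i in range(config.n_libraries)}
    return SimulatedDataset(
        genes=genes, true_pair_ks=true_pair_ks, true_family_ids=true_family_ids,
        true_coregulation=truth_coreg, counts=counts, tissue_map=tissue_map,
        config=config,
    )
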