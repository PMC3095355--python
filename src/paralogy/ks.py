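"""Pairwise synonymous-divergence (Ks) estimation under a codon model.

The estimator follows the Goldman-Yang (GY94) codon substitution model with
F3x4 equilibrium frequencies: for a pair of aligned coding sequences the
divergence ``t`` (expected substitutions per codon), the transition/
transversion ratio ``kappa`` and the selection ratio ``omega`` are estimated
jointly by maximum likelihood, and Ks / Ka are derived from the synonymous
and nonsynonymous substitution flux of the fitted rate matrix.

An independent Nei-Gojobori (1986) pathway-counting estimator with
Jukes-Cantor correction is provided as a cross-check; it shares no code with
the likelihood machinery beyond the genetic-code tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import minimize

from ._codons import (
    AMINO_ACID,
    CODON_INDEX,
    DIFF_DST,
    DIFF_IS_SYN,
    DIFF_IS_TS,
    DIFF_SRC,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    codons_of,
    empirical_position_freqs,
    f3x4_codon_frequencies,
    is_transition,
    translate_codon,
)

__all__ = [
    "CodonModel",
    "KsEstimate",
    "Ng86Result",
    "codon_align",
    "fit_pair_ml",
    "ng86_ks",
    "filter_ks",
]

_PI_FLOOR = 1e-8

# parameter bounds for the ML search (natural scale)
T_BOUNDS = (1e-6, 20.0)
KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 10.0)


class CodonModel:
    """GY94 instantaneous rate matrix over the 61 sense codons.

    The matrix is scaled so that the expected number of substitutions per
    codon per unit time is one (``-sum_i pi_i q_ii = 1``), which makes the
    divergence parameter ``t`` directly interpretable as substitutions per
    codon.
    """

    def __init__(self, pi: np.ndarray, kappa: float, omega: float):
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (N_SENSE,):
            raise ValueError(f"pi must have length {N_SENSE}")
        if np.any(pi < 0) or pi.sum() <= 0:
            raise ValueError("pi must be a non-negative vector with positive mass")
        # floor to keep the reversible similarity transform well conditioned
        pi = np.maximum(pi / pi.sum(), _PI_FLOOR)
        self.pi = pi / pi.sum()
        self.kappa = float(kappa)
        self.omega = float(omega)

        rates = self.pi[DIFF_DST].copy()
        rates[DIFF_IS_TS] *= self.kappa
        rates[~DIFF_IS_SYN] *= self.omega
        Q = np.zeros((N_SENSE, N_SENSE))
        Q[DIFF_SRC, DIFF_DST] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.dot(self.pi, np.diag(Q)))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (zero total flux)")
        Q /= scale
        self.Q = Q

        # synonymous fraction of the substitution flux: sum over synonymous
        # ordered pairs of pi_i * q_ij (total off-diagonal flux is 1)
        flux = self.pi[DIFF_SRC] * Q[DIFF_SRC, DIFF_DST]
        self.rho_syn = float(flux[DIFF_IS_SYN].sum())

        # reversible similarity transform: B = D^1/2 Q D^-1/2 is symmetric
        sqrt_pi = np.sqrt(self.pi)
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]
        self._right = (evecs * sqrt_pi[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("t must be non-negative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 1e-300, None, out=P)
        return P


@dataclass(frozen=True)
class KsEstimate:
    """Maximum-likelihood output for one paralog pair."""

    t: float
    kappa: float
    omega: float
    ks: float
    ka: float
    loglik: float
    n_codons_used: int
    converged: bool = True
    flags: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class Ng86Result:
    """Counting-method estimate: proportions, JC-corrected distances."""

    ks: float
    ka: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool = False

    def __iter__(self):
        return iter((self.ks, self.ka))


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(cds_a: str, cds_b: str, protein_a: str | None = None,
                protein_b: str | None = None) -> list[tuple[str, str]]:
    """Align two CDS at the codon level via their protein sequences.

    The proteins are aligned globally and the alignment is back-translated to
    codons; columns containing a gap, an ambiguous base or a stop codon are
    removed.  If proteins are not supplied they are translated from the CDS.

    Raises ``ValueError`` when a supplied protein is inconsistent with its CDS.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    codons_a, codons_b = codons_of(cds_a), codons_of(cds_b)
    trans_a = "".join(_safe_aa(c) for c in codons_a)
    trans_b = "".join(_safe_aa(c) for c in codons_b)
    if protein_a is None:
        protein_a = trans_a.rstrip("*")
    if protein_b is None:
        protein_b = trans_b.rstrip("*")
    _check_consistent(trans_a, protein_a, "first")
    _check_consistent(trans_b, protein_b, "second")

    # align on X/stop-sanitized proteins so BLOSUM lookups never fail
    aln = _protein_aligner().align(
        protein_a.replace("*", "X"), protein_b.replace("*", "X")
    )[0]
    columns: list[tuple[str, str]] = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for off in range(ea - sa):
            ca = codons_a[sa + off]
            cb = codons_b[sb + off]
            if _clean_codon(ca) and _clean_codon(cb):
                columns.append((ca, cb))
    return columns


def _safe_aa(codon: str) -> str:
    if any(b not in "ACGT" for b in codon):
        return "X"
    return translate_codon(codon)


def _clean_codon(codon: str) -> bool:
    return all(b in "ACGT" for b in codon) and codon not in STOP_CODONS


def _check_consistent(translated: str, protein: str, which: str) -> None:
    prot = protein.rstrip("*")
    if len(prot) > len(translated):
        raise ValueError(f"{which} protein longer than its CDS allows")
    for aa_t, aa_p in zip(translated, prot):
        if "X" in (aa_t, aa_p):
            continue
        if aa_t != aa_p:
            raise ValueError(
                f"{which} CDS does not translate to the supplied protein"
            )


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def _pair_counts(columns) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse aligned codon columns to unique (i, j) index pairs + counts."""
    seen: dict[tuple[int, int], int] = {}
    for ca, cb in columns:
        key = (CODON_INDEX[ca], CODON_INDEX[cb])
        seen[key] = seen.get(key, 0) + 1
    idx = np.array(list(seen.keys()), dtype=np.intp).reshape(-1, 2)
    counts = np.array(list(seen.values()), dtype=float)
    return idx[:, 0], idx[:, 1], counts


def _loglik(t: float, kappa: float, omega: float, pi, ii, jj, counts) -> float:
    model = CodonModel(pi, kappa, omega)
    P = model.transition_matrix(t)
    return float(np.dot(counts, np.log(model.pi[ii] * P[ii, jj])))


def ks_ka_from_model(t: float, pi: np.ndarray, kappa: float, omega: float):
    """Decompose divergence t into Ks and Ka via substitution-flux fractions.

    ``rho_syn`` is the synonymous fraction of flux under the fitted model and
    ``rho_syn(omega=1)`` the same under neutrality; three times the latter is
    the proportion of synonymous sites per codon, so
    ``Ks = t * rho_syn / (3 * rho_syn^1)`` and analogously for Ka.
    """
    rho = CodonModel(pi, kappa, omega).rho_syn
    rho1 = CodonModel(pi, kappa, 1.0).rho_syn
    ks = t * rho / (3.0 * rho1)
    ka = t * (1.0 - rho) / (3.0 * (1.0 - rho1))
    return ks, ka


def _restart_starts(n_restarts: int, rng: np.random.Generator):
    base_t = [0.05, 0.2, 0.5, 1.0, 2.0]
    starts = []
    for r in range(n_restarts):
        t0 = base_t[r % len(base_t)] * rng.uniform(0.8, 1.2)
        kappa0 = 2.0
        omega0 = 0.3 * rng.uniform(0.8, 1.2)
        starts.append((t0, kappa0, omega0))
    return starts


def fit_pair_ml(columns, n_restarts: int = 5, seed: int | None = None) -> KsEstimate:
    """Fit (t, kappa, omega) by ML for one aligned codon-column list.

    F3x4 frequencies are estimated empirically from the pair itself.  The
    optimizer is a bounded Nelder-Mead on log-transformed parameters with
    ``n_restarts`` randomized initializations; the best log-likelihood wins.
    """
    columns = list(columns)
    if len(columns) < 10:
        raise ValueError(f"need at least 10 codon columns, got {len(columns)}")

    counting = ng86_ks(columns)
    pi = f3x4_codon_frequencies(
        empirical_position_freqs(
            "".join(a for a, _ in columns), "".join(b for _, b in columns)
        )
    )
    ii, jj, counts = _pair_counts(columns)
    n_used = len(columns)

    if counting.syn_diffs == 0 and counting.nonsyn_diffs == 0:
        # identical over the retained columns: the MLE of t is exactly zero
        model = CodonModel(pi, 2.0, OMEGA_BOUNDS[0])
        ll = float(np.dot(counts, np.log(model.pi[ii])))
        return KsEstimate(0.0, 2.0, OMEGA_BOUNDS[0], 0.0, 0.0, ll, n_used,
                          flags=("identical",))

    rng = np.random.default_rng(seed)
    lo = np.log([T_BOUNDS[0], KAPPA_BOUNDS[0], OMEGA_BOUNDS[0]])
    hi = np.log([T_BOUNDS[1], KAPPA_BOUNDS[1], OMEGA_BOUNDS[1]])

    def neg_ll(x):
        t, kappa, omega = np.exp(np.clip(x, lo, hi))
        return -_loglik(t, kappa, omega, pi, ii, jj, counts)

    best = None
    any_converged = False
    for t0, kappa0, omega0 in _restart_starts(n_restarts, rng):
        x0 = np.log([t0, kappa0, omega0])
        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    t, kappa, omega = np.exp(np.clip(best.x, lo, hi))
    ks, ka = ks_ka_from_model(t, pi, kappa, omega)
    flags = []
    if not any_converged:
        flags.append("nonconverged")
    # observed-difference snap: with no synonymous (nonsynonymous)
    # differences the corresponding distance's MLE lies on the zero boundary
    if counting.syn_diffs == 0:
        ks = 0.0
    if counting.nonsyn_diffs == 0:
        ka = 0.0
    return KsEstimate(
        float(t), float(kappa), float(omega), float(ks), float(ka),
        -float(best.fun), n_used, converged=any_converged, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# NG86 counting oracle
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon (normalized to 3).

    Mutations creating stop codons count as nonsynonymous, matching the
    common implementation convention (MEGA, Biopython).
    """
    syn = nonsyn = 0.0
    aa = AMINO_ACID[codon]
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            neighbor = codon[:p] + b + codon[p + 1 :]
            if neighbor in STOP_CODONS:
                nonsyn += 1.0
            elif AMINO_ACID[neighbor] == aa:
                syn += 1.0
            else:
                nonsyn += 1.0
    total = syn + nonsyn
    return 3.0 * syn / total, 3.0 * nonsyn / total


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average syn/nonsyn difference counts over all mutational pathways."""
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    if not diff_pos:
        return 0.0, 0.0

    def step(c1, c2):
        aa1 = "*" if c1 in STOP_CODONS else AMINO_ACID[c1]
        aa2 = "*" if c2 in STOP_CODONS else AMINO_ACID[c2]
        return (1.0, 0.0) if aa1 == aa2 else (0.0, 1.0)

    syn = nonsyn = 0.0
    paths = list(permutations(diff_pos))
    for path in paths:
        cur = ca
        for p in path:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            s, n = step(cur, nxt)
            syn += s
            nonsyn += n
            cur = nxt
    k = float(len(paths))
    return syn / k, nonsyn / k


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_ks(columns) -> Ng86Result:
    """Nei-Gojobori (1986) Ks/Ka by pathway counting with JC correction.

    Returns NaN distances (with ``saturated=True``) when the observed
    proportion of differences reaches the Jukes-Cantor ceiling of 3/4.
    """
    columns = list(columns)
    if not columns:
        raise ValueError("empty codon alignment")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for ca, cb in columns:
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        ds, dn = _pathway_diffs(ca, cb)
        s_diff += ds
        n_diff += dn
    ps = s_diff / s_sites if s_sites > 0 else 0.0
    pn = n_diff / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    return Ng86Result(ks, ka, s_sites, n_sites, s_diff, n_diff, saturated)


# ---------------------------------------------------------------------------
# downstream filtering
# ---------------------------------------------------------------------------

def filter_ks(estimates: dict, ks_max: float = 2.0):
    """Apply the saturation filter to a mapping pair -> KsEstimate.

    Returns ``(retained, zero_ks_pairs)``: estimates with ``Ks > ks_max``
    (saturation-prone) or non-converged fits are dropped; pairs with Ks = 0
    are returned separately for redundancy cleanup (they are likely multiple
    entries of the same gene).  The boundary is inclusive: Ks equal to
    ``ks_max`` is retained.
    """
    retained: dict = {}
    zero_pairs: list = []
    for pair, est in estimates.items():
        if not est.converged or not math.isfinite(est.ks):
            continue
        if est.ks > ks_max:
            continue
        if est.ks == 0.0:
            zero_pairs.append(pair)
        retained[pair] = est
    return retained, zero_pairs
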