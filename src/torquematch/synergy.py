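"""Muscle-synergy pipeline: activity-matrix assembly, two-stage
normalization, NMF, VAF model selection, random-synergy similarity null,
and cross-participant synergy matching.

The per-participant activity matrix ``A`` holds the mean percent-MVC
envelope of 8 muscles over 48 cells (2 phases x 8 analyzed trials x 3
loads).  Each row is first scaled to a maximum of 1, then to unit sample
variance.  ``A`` is factorized as ``A = W H`` with ``W`` (8 x n) the
nonnegative synergy vectors and ``H`` (n x 48) their activation
coefficients; ``n`` is the smallest count whose reconstruction reaches a
variance-accounted-for (VAF) of 95 %.

The factorization minimizes the squared Frobenius error with
multiplicative update rules, restarted from several seeded random
initializations; ``W`` columns are unit-normalized (Euclidean) with the
compensating scale folded into ``H``, which makes scalar products between
synergy vectors well-defined cosine similarities.

Synergies are compared across participants against the 95th percentile of
the pairwise scalar products of 1000 random nonnegative unit vectors (all
ordered pairs, 10^6 values); matching is greedy best-first against a
reference participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from torquematch.config import MUSCLES, N_MUSCLES
from torquematch.features import PHASES, TrialFeatures

_EPS = 1e-12


@dataclass
class ActivityMatrix:
    """Nonnegative 8 x 48 muscle-activity matrix with cell labels."""

    values: np.ndarray
    column_labels: list[tuple[str, int, float]]  # (phase, trial, load)
    row_scale: np.ndarray | None = None  # applied per-row divisors

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_MUSCLES:
            raise ValueError(f"activity matrix must have {N_MUSCLES} rows")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("one label per column required")
        if np.any(self.values < 0):
            raise ValueError("activity matrix must be nonnegative")


@dataclass
class SynergyModel:
    """A fitted factorization with its model-selection trace."""

    W: np.ndarray               # (8, n), unit-norm columns
    H: np.ndarray               # (n, 48)
    n: int
    vaf: float
    vaf_curve: np.ndarray       # VAF at n = 1..n_max
    converged: bool
    seed: int
    threshold_reached: bool = True


@dataclass
class GroupSynergyResult:
    """Cross-participant synergy matching against a reference."""

    threshold: float
    reference_participant: str
    matches: dict[str, dict[int, int | None]]  # pid -> {own idx: ref idx}
    mean_W: np.ndarray
    mean_H: np.ndarray
    n_matched: np.ndarray = field(default=None)  # per reference synergy


def assemble_matrix(features: list[TrialFeatures],
                    trials_per_load: int = 8,
                    strict: bool = True) -> ActivityMatrix:
    """Build the 8 x 48 activity matrix for one participant.

    Columns are ordered load ascending, trial ascending, phase
    (reference, match).  Only valid trials carrying phase-averaged
    envelopes are used; in strict mode an incomplete participant is
    rejected with the missing (load, trial) cells named.
    """
    usable = [f for f in features if f.valid and f.mean_norm_emg is not None]
    loads = sorted({f.load_condition for f in features})
    by_cell = {(f.load_condition, f.trial_index): f for f in usable}
    columns, labels, missing = [], [], []
    for load in loads:
        trials = sorted(t for (l, t) in by_cell if l == load)
        if len(trials) < trials_per_load:
            missing.extend((load, None) for _ in
                           range(trials_per_load - len(trials)))
        for trial in trials[:trials_per_load]:
            f = by_cell[(load, trial)]
            for p, phase in enumerate(PHASES):
                columns.append(f.mean_norm_emg[:, p])
                labels.append((phase, trial, load))
    if missing and strict:
        cells = ", ".join(f"(load={l}, trial={t})" for l, t in missing)
        raise ValueError(f"incomplete participant; missing cells: {cells}")
    return ActivityMatrix(values=np.column_stack(columns),
                          column_labels=labels)


def normalize_matrix(a: ActivityMatrix) -> ActivityMatrix:
    """Two-stage row normalization: divide by the row max (range [0, 1]),
    then by the row sample SD (unit variance).  Scales are recorded so
    the transform can be inverted."""
    values = a.values.copy()
    row_max = values.max(axis=1)
    if np.any(row_max == 0):
        dead = [MUSCLES[i] for i in np.where(row_max == 0)[0]]
        raise ValueError(f"all-zero rows cannot be normalized: {dead}")
    values /= row_max[:, None]
    row_sd = values.std(axis=1, ddof=1)
    if np.any(row_sd == 0):
        flat = [MUSCLES[i] for i in np.where(row_sd == 0)[0]]
        raise ValueError(f"constant rows have zero variance: {flat}")
    values /= row_sd[:, None]
    return ActivityMatrix(values=values, column_labels=list(a.column_labels),
                          row_scale=row_max * row_sd)


def _mu_nmf(a: np.ndarray, n: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray,
                                                float, bool]:
    """One multiplicative-update run for the Frobenius objective."""
    rows, cols = a.shape
    scale = np.sqrt(a.mean() / n)
    w = scale * rng.random((rows, n)) + _EPS
    h = scale * rng.random((n, cols)) + _EPS
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        h *= (w.T @ a) / (w.T @ w @ h + _EPS)
        w *= (a @ h.T) / (w @ (h @ h.T) + _EPS)
        err = float(np.linalg.norm(a - w @ h) ** 2)
        if prev < np.inf and abs(prev - err) <= tol * max(prev, _EPS):
            converged = True
            break
        prev = err
    return w, h, err, converged


def nmf_decompose(a: np.ndarray, n: int, seed: int = 0,
                  restarts: int = 20, max_iter: int = 2000,
                  tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, bool]:
    """Nonnegative factorization A ~ W H by multiplicative updates.

    Best of ``restarts`` seeded initializations; returned ``W`` columns
    are unit Euclidean norm with the scale folded into ``H``.  Returns
    (W, H, converged); a non-converged best run is still returned.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("NMF requires a nonnegative matrix")
    if not 1 <= n <= a.shape[0]:
        raise ValueError("synergy count must lie in [1, n_muscles]")
    ss = np.random.SeedSequence([seed, n])
    best = None
    for child in ss.spawn(restarts):
        w, h, err, conv = _mu_nmf(a, n, np.random.default_rng(child),
                                  max_iter, tol)
        if best is None or err < best[2]:
            best = (w, h, err, conv)
    w, h, _, converged = best
    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    return w / norms, h * norms[:, None], converged


def compute_vaf(a: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    """Variance accounted for: 1 - ||A - WH||_F^2 / ||A||_F^2 (uncentered).

    The centered variant (residual SS over SS around the grand mean) is
    available via :func:`compute_vaf_centered`.
    """
    a = np.asarray(a, dtype=float)
    total = float(np.linalg.norm(a) ** 2)
    if total == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    resid = float(np.linalg.norm(a - w @ h) ** 2)
    return 1.0 - resid / total


def compute_vaf_centered(a: np.ndarray, w: np.ndarray,
                         h: np.ndarray) -> float:
    """VAF on sums of squares centered at the grand mean."""
    a = np.asarray(a, dtype=float)
    total = float(np.sum((a - a.mean()) ** 2))
    if total == 0:
        raise ValueError("centered VAF undefined for a constant matrix")
    resid = float(np.linalg.norm(a - w @ h) ** 2)
    return 1.0 - resid / total


def select_synergy_count(a: np.ndarray, vaf_threshold: float = 0.95,
                         seed: int = 0, restarts: int = 20,
                         max_iter: int = 2000,
                         tol: float = 1e-6) -> SynergyModel:
    """Fit n = 1..8 and keep the smallest model reaching the VAF
    threshold.

    If even the full model misses the threshold, the 8-synergy model is
    returned with ``threshold_reached`` False.
    """
    a = np.asarray(a, dtype=float)
    n_max = a.shape[0]
    vaf_curve = np.empty(n_max)
    fits = []
    selected = None
    for n in range(1, n_max + 1):
        w, h, conv = nmf_decompose(a, n, seed=seed, restarts=restarts,
                                   max_iter=max_iter, tol=tol)
        vaf_curve[n - 1] = compute_vaf(a, w, h)
        fits.append((w, h, conv))
        if selected is None and vaf_curve[n - 1] >= vaf_threshold:
            selected = n
            break
    reached = selected is not None
    if selected is None:
        selected = n_max
        for n in range(len(fits) + 1, n_max + 1):  # pragma: no cover
            w, h, conv = nmf_decompose(a, n, seed=seed, restarts=restarts,
                                       max_iter=max_iter, tol=tol)
            vaf_curve[n - 1] = compute_vaf(a, w, h)
            fits.append((w, h, conv))
    w, h, conv = fits[selected - 1]
    return SynergyModel(W=w, H=h, n=selected,
                        vaf=float(vaf_curve[selected - 1]),
                        vaf_curve=vaf_curve[:len(fits)].copy(),
                        converged=conv, seed=seed,
                        threshold_reached=reached)


def random_synergy_products(dim: int = 8, n_random: int = 1000,
                            seed: int = 0,
                            include_self_pairs: bool = True) -> np.ndarray:
    """Null distribution of scalar products between random synergies.

    Draws ``n_random`` nonnegative unit vectors (coordinates Uniform(0,1),
    normalized to unit Euclidean norm) and returns all ordered pairwise
    scalar products — n_random^2 values (10^6 at the default), self-pairs
    included; ``include_self_pairs=False`` gives the n(n-1) off-diagonal
    sensitivity variant.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    rng = np.random.default_rng(seed)
    v = rng.random((n_random, dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    products = v @ v.T
    if not include_self_pairs:
        products = products[~np.eye(n_random, dtype=bool)]
    return products.ravel()


def random_synergy_threshold(dim: int = 8, n_random: int = 1000,
                             percentile: float = 95.0, seed: int = 0,
                             include_self_pairs: bool = True) -> float:
    """Similarity threshold: the given percentile of the random-synergy
    scalar-product null distribution (95th of 10^6 values by default)."""
    products = random_synergy_products(dim, n_random, seed,
                                       include_self_pairs)
    return float(np.percentile(products, percentile))


def match_synergies(models: dict[str, SynergyModel], threshold: float,
                    reference: str) -> GroupSynergyResult:
    """Greedy best-first matching of each participant's synergies to a
    reference participant's, accepting pairs whose scalar product meets
    the threshold; each reference synergy is used at most once per
    participant.  Matched vectors/coefficients are averaged (reference
    included) into group-mean synergies."""
    if reference not in models:
        raise ValueError(f"reference participant {reference!r} not in models")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    ref_model = models[reference]
    n_ref = ref_model.n
    w_sets: list[list[np.ndarray]] = [[ref_model.W[:, j]]
                                      for j in range(n_ref)]
    h_sets: list[list[np.ndarray]] = [[ref_model.H[j]]
                                      for j in range(n_ref)]
    matches: dict[str, dict[int, int | None]] = {}
    for pid, model in models.items():
        if pid == reference:
            continue
        sims = model.W.T @ ref_model.W  # (n_own, n_ref)
        assignment: dict[int, int | None] = {i: None
                                             for i in range(model.n)}
        order = np.dstack(np.unravel_index(
            np.argsort(sims, axis=None)[::-1], sims.shape))[0]
        used_own, used_ref = set(), set()
        for i, j in order:
            if sims[i, j] < threshold:
                break
            if i in used_own or j in used_ref:
                continue
            assignment[int(i)] = int(j)
            used_own.add(int(i))
            used_ref.add(int(j))
            w_sets[j].append(model.W[:, i])
            if model.H.shape[1] == ref_model.H.shape[1]:
                h_sets[j].append(model.H[i])
        matches[pid] = assignment
    mean_w = np.column_stack([np.mean(s, axis=0) for s in w_sets])
    mean_h = np.vstack([np.mean(s, axis=0) for s in h_sets])
    return GroupSynergyResult(
        threshold=threshold, reference_participant=reference,
        matches=matches, mean_W=mean_w, mean_H=mean_h,
        n_matched=np.array([len(s) for s in w_sets]),
    )


def synergy_tables(model: SynergyModel,
                   labels: list[tuple[str, int, float]] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """W and H as labeled DataFrames for TSV export."""
    w = pd.DataFrame(model.W, index=list(MUSCLES),
                     columns=[f"synergy_{j + 1}" for j in range(model.n)])
    cols = ([f"{ph}_load{load:g}_trial{tr}" for ph, tr, load in labels]
            if labels is not None else
            [f"cell_{c}" for c in range(model.H.shape[1])])
    h = pd.DataFrame(model.H, columns=cols,
                     index=[f"synergy_{j + 1}" for j in range(model.n)])
    return w, h
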