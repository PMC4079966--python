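"""Three-state HMM segmentation of the genome into replication domains.

The observation at each 5-kb window (stepped every 1 kb) is the bivariate
(early, late) fraction signal — chromosome-normalized, percentile-capped
RPKM. Three hidden states (early, late, indeterminate replication) each emit
a bivariate normal. Emission parameters are seeded empirically by k-means
(k = 3) on the per-window log2 early/late ratio; transition probabilities
start heavily self-biased and initial probabilities uniform. Each chromosome
is then trained separately by Baum-Welch until the log-likelihood gain drops
below 0.05, decoded with the Viterbi algorithm, and post-processed by
iteratively merging state runs shorter than 40 windows (~45 kb) into their
larger neighbouring run, compensating for BrdU-incorporation kinetics and
fork speed. Maximal same-state runs become labeled domain intervals.

All recursions are run with per-position scaling or in log space; this is
part of the numerical contract, not an implementation detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .binning import BinGrid

#: semantic labels ordered by mean log2(early/late) ratio of the seeding clusters
STATE_LABELS = ("late", "indeterminate", "early")


@dataclass
class EmissionParams:
    """Bivariate-normal emission per state: mean (early, late) and covariance."""

    means: np.ndarray  # (k, 2)
    covs: np.ndarray  # (k, 2, 2)

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.covs = np.asarray(self.covs, float)
        if self.means.shape[0] != self.covs.shape[0]:
            raise ValueError("means and covs disagree on state count")

    @property
    def n_states(self) -> int:
        return self.means.shape[0]


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Ensure positive definiteness by adding eps·I scaled to the mean variance."""
    cov = np.asarray(cov, float)
    cov = (cov + cov.T) / 2
    eps = 1e-6 * max(np.mean(np.diag(cov)), 1e-12)
    for _ in range(12):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            cov = cov + eps * np.eye(cov.shape[0])
            eps *= 10
    raise np.linalg.LinAlgError("covariance could not be regularized")


def _clip_eigenvalues(cov: np.ndarray, floor: float) -> np.ndarray:
    """Project a symmetric matrix onto {Σ : eigenvalues ≥ floor}.

    This is the constrained maximizer of the Gaussian likelihood over that
    set, so using it as the M-step keeps EM monotone while preventing the
    covariance collapse that occurs when a state's signal channel is almost
    constant (e.g. the early channel inside late domains).
    """
    cov = (np.asarray(cov, float) + np.asarray(cov, float).T) / 2
    vals, vecs = np.linalg.eigh(cov)
    return (vecs * np.maximum(vals, floor)) @ vecs.T


def _gaussian_logpdf(obs: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate-normal log density via Cholesky."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(_regularize(cov))
    diff = np.atleast_2d(obs) - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2 * np.log(np.diag(chol)).sum()
    d = cov.shape[0]
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


@dataclass
class SegmentationModel:
    """Full 3-state HMM: initial, transition and emission parameters.

    ``state_labels[i]`` is the semantic label of state i; after training the
    mapping is refreshed by ranking states on (mean early − mean late).
    ``loglik_trace`` records per-iteration log-likelihoods of the most recent
    training run.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    emissions: EmissionParams
    state_labels: tuple[str, ...] = STATE_LABELS
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.startprob = np.asarray(self.startprob, float)
        self.transmat = np.asarray(self.transmat, float)
        if not np.allclose(self.startprob.sum(), 1):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.transmat.sum(axis=1), 1):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """(n, k) log density of each observation under each state."""
        obs = np.atleast_2d(np.asarray(obs, float))
        out = np.empty((obs.shape[0], self.n_states))
        for i in range(self.n_states):
            out[:, i] = _gaussian_logpdf(
                obs, self.emissions.means[i], self.emissions.covs[i]
            )
        return out

    def relabel_by_ratio(self) -> "SegmentationModel":
        """Assign semantic labels by ranking states on mean(early) − mean(late)."""
        diff = self.emissions.means[:, 0] - self.emissions.means[:, 1]
        order = np.argsort(diff)  # ascending: late, indeterminate, early
        labels = [""] * self.n_states
        for rank, state in enumerate(order):
            labels[state] = STATE_LABELS[rank]
        return replace(self, state_labels=tuple(labels))

    def to_dict(self) -> dict:
        return {
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.emissions.means.tolist(),
            "covs": self.emissions.covs.tolist(),
            "state_labels": list(self.state_labels),
            "loglik_trace": list(map(float, self.loglik_trace)),
        }


def init_kmeans(
    ratio: np.ndarray,
    el_values: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    self_transition: float = 0.998,
) -> SegmentationModel:
    """Seed the HMM from k-means clusters of the 1-D log2(early/late) ratio.

    Each cluster's member windows supply the empirical bivariate mean and
    covariance of the (early, late) signal for one state. Clusters are ordered
    by mean ratio and labeled late / indeterminate / early. Transitions start
    self-biased and initial probabilities uniform.
    """
    ratio = np.asarray(ratio, float)
    el_values = np.asarray(el_values, float)
    finite = np.isfinite(ratio) & np.isfinite(el_values).all(axis=1)
    r, el = ratio[finite], el_values[finite]
    if np.unique(r).size < k:
        raise ValueError(f"need at least {k} distinct finite ratio values")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(r[:, None])
    assign = km.labels_
    order = np.argsort([r[assign == c].mean() for c in range(k)])
    means = np.empty((k, 2))
    covs = np.empty((k, 2, 2))
    for rank, c in enumerate(order):
        pts = el[assign == c]
        means[rank] = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False) if len(pts) > 1 else np.eye(2)
        cov = np.atleast_2d(cov)
        if not np.all(np.isfinite(cov)):
            cov = np.eye(2)
        if np.linalg.det(cov) <= 0:
            warnings.warn("singular within-cluster covariance; regularizing")
        floor = 1e-3 * max(float(el.var(axis=0).mean()), 1e-12)
        covs[rank] = _clip_eigenvalues(cov, floor)
    off = (1 - self_transition) / (k - 1)
    transmat = np.full((k, k), off)
    np.fill_diagonal(transmat, self_transition)
    return SegmentationModel(
        startprob=np.full(k, 1 / k),
        transmat=transmat,
        emissions=EmissionParams(means=means, covs=covs),
    )


def _forward_backward(model: SegmentationModel, logb: np.ndarray):
    """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
    n, k = logb.shape
    shift = logb.max(axis=1)
    b = np.exp(logb - shift[:, None])  # per-row rescaled emission densities
    alpha = np.empty((n, k))
    c = np.empty(n)
    a = model.transmat
    alpha[0] = model.startprob * b[0]
    c[0] = alpha[0].sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise FloatingPointError("non-finite likelihood at bin 0")
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ a) * b[t]
        c[t] = alpha[t].sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise FloatingPointError(f"non-finite likelihood at bin {t}")
        alpha[t] /= c[t]
    beta = np.empty((n, k))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (a @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi summed over t, fully vectorized
    bb = (b[1:] * beta[1:]) / c[1:, None]
    xi_sum = (alpha[:-1].T @ bb) * a
    loglik = float(np.log(c).sum() + shift.sum())
    return loglik, gamma, xi_sum


def baum_welch_train(
    obs: np.ndarray,
    model: SegmentationModel,
    tol: float = 0.05,
    max_iter: int = 500,
) -> SegmentationModel:
    """EM re-estimation of all HMM parameters on one chromosome's observations.

    Iterates until the log-likelihood improvement falls below ``tol`` (the
    trace is monotone non-decreasing up to floating-point slack) or the
    iteration cap is reached, keeping covariance estimates positive definite
    by epsilon-regularization. Returns a new model carrying the trace.
    """
    obs = np.asarray(obs, float)
    if obs.ndim != 2 or obs.shape[0] < 2:
        raise ValueError("need a (n >= 2, 2) observation matrix")
    # fixed covariance-eigenvalue floor for the whole run (constrained M-step)
    floor = 1e-3 * max(float(obs.var(axis=0).mean()), 1e-12)
    model = replace(
        model,
        startprob=model.startprob.copy(),
        transmat=model.transmat.copy(),
        emissions=EmissionParams(
            model.emissions.means.copy(),
            # bring the incoming model into the constrained parameter set so
            # the EM ascent guarantee holds from the first iteration
            np.stack([_clip_eigenvalues(c, floor) for c in model.emissions.covs]),
        ),
        loglik_trace=[],
    )
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        logb = model.log_emission(obs)
        loglik, gamma, xi_sum = _forward_backward(model, logb)
        trace.append(loglik)
        # M-step
        model.startprob = gamma[0] / gamma[0].sum()
        denom = gamma[:-1].sum(axis=0)[:, None]
        transmat = np.where(denom > 0, xi_sum / np.maximum(denom, 1e-300), model.transmat)
        transmat /= transmat.sum(axis=1, keepdims=True)
        model.transmat = transmat
        occ = gamma.sum(axis=0)
        for i in range(model.n_states):
            if occ[i] < 1e-8:  # starved state: keep previous parameters
                continue
            mu = gamma[:, i] @ obs / occ[i]
            diff = obs - mu
            cov = (gamma[:, i] * diff.T) @ diff / occ[i]
            model.emissions.means[i] = mu
            model.emissions.covs[i] = _clip_eigenvalues(cov, floor)
        # an infinite tolerance means "accept any improvement": one EM sweep
        if np.isinf(tol) or loglik - prev < tol:
            break
        prev = loglik
    else:
        warnings.warn(f"Baum-Welch reached the {max_iter}-iteration cap")
    model.loglik_trace = trace
    return model


def posteriors(obs: np.ndarray, model: SegmentationModel) -> np.ndarray:
    """Posterior state probabilities gamma, shape (n, k)."""
    _, gamma, _ = _forward_backward(model, model.log_emission(np.asarray(obs, float)))
    return gamma


def viterbi_decode(obs: np.ndarray, model: SegmentationModel) -> np.ndarray:
    """Most probable state path in log space; ties resolve to the lower state index."""
    obs = np.asarray(obs, float)
    if obs.size == 0:
        return np.empty(0, dtype=int)
    logb = model.log_emission(obs)
    n, k = logb.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(model.startprob)
        loga = np.log(model.transmat)
    delta = logpi + logb[0]
    psi = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + loga
        psi[t] = np.argmax(cand, axis=0)  # first max → lowest index on ties
        delta = cand[psi[t], np.arange(k)] + logb[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def path_logprob(obs: np.ndarray, path: np.ndarray, model: SegmentationModel) -> float:
    """Joint log probability of a given state path and the observations."""
    logb = model.log_emission(np.asarray(obs, float))
    with np.errstate(divide="ignore"):
        lp = np.log(model.startprob[path[0]]) + logb[0, path[0]]
        for t in range(1, len(path)):
            lp += np.log(model.transmat[path[t - 1], path[t]]) + logb[t, path[t]]
    return float(lp)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode: list of (state, start_idx, length)."""
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    return [
        (int(states[bounds[i]]), int(bounds[i]), int(bounds[i + 1] - bounds[i]))
        for i in range(len(bounds) - 1)
    ]


def merge_short_runs(states: np.ndarray, min_run: int = 40) -> np.ndarray:
    """Iteratively absorb sub-threshold state runs into their larger neighbour.

    The globally shortest run below ``min_run`` is relabeled to the longer of
    its two flanking runs (left wins ties; chromosome ends have one flank),
    runs are re-merged, and the scan repeats until every run reaches
    ``min_run`` or a single run spans the chromosome.
    """
    states = np.asarray(states).copy()
    while True:
        runs = _runs(states)
        if len(runs) <= 1:
            return states
        short = [(length, i) for i, (_, _, length) in enumerate(runs) if length < min_run]
        if not short:
            return states
        _, i = min(short)  # shortest run; ties → leftmost
        state, start, length = runs[i]
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i < len(runs) - 1 else None
        if left is None:
            new_state = right[0]
        elif right is None:
            new_state = left[0]
        else:
            new_state = left[0] if left[2] >= right[2] else right[0]
        states[start : start + length] = new_state


@dataclass
class DomainSet:
    """Labeled replication-domain intervals for one sample."""

    intervals: pd.DataFrame  # chrom, start, end, label, score
    sample: str = ""
    model_params: dict | None = None

    def __post_init__(self):
        iv = self.intervals
        for chrom, sub in iv.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping domain intervals on {chrom}")

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Label per position; 'none' where no domain covers the position."""
        sub = self.intervals[self.intervals["chrom"] == chrom].sort_values("start")
        out = np.full(len(positions), "none", dtype=object)
        idx = np.searchsorted(sub["start"].to_numpy(), positions, side="right") - 1
        valid = idx >= 0
        covered = valid & (positions < sub["end"].to_numpy()[idx.clip(min=0)])
        out[covered] = sub["label"].to_numpy()[idx[covered]]
        return out


def states_to_domains(
    states: np.ndarray,
    chrom: str,
    grid: BinGrid,
    model: SegmentationModel,
    gamma: np.ndarray | None = None,
) -> pd.DataFrame:
    """Collapse a merged per-window state path into labeled intervals.

    Each 1-kb step carries its window's label; a maximal run of windows
    [i, j] becomes the interval [start_i, start_j + step). The score column
    is the mean posterior of the assigned state over the run (0 if posteriors
    are not supplied).
    """
    starts = grid.starts(chrom)
    rows = []
    for state, start_idx, length in _runs(states):
        lo = int(starts[start_idx])
        hi = int(starts[start_idx + length - 1]) + grid.step
        score = float(gamma[start_idx : start_idx + length, state].mean()) if gamma is not None else 0.0
        rows.append((chrom, lo, hi, model.state_labels[state], round(score, 4)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"])


def segment_genome(
    signal,
    ratio: np.ndarray,
    seed: int = 0,
    tol: float = 0.05,
    min_run: int = 40,
    self_transition: float = 0.998,
    sample: str = "",
    max_iter: int = 500,
) -> tuple[DomainSet, dict[str, SegmentationModel]]:
    """Full segmentation of a chromosome-normalized, capped (early, late) signal.

    A genome-wide k-means initialization seeds per-chromosome Baum-Welch
    training; each chromosome is decoded under its own trained model (with
    labels re-ranked by emission mean difference), short runs are merged, and
    runs become domains. Returns the DomainSet and the per-chromosome models.
    """
    el = np.stack([signal.fraction("early"), signal.fraction("late")], axis=1)
    init = init_kmeans(ratio, el, seed=seed, self_transition=self_transition)
    models: dict[str, SegmentationModel] = {}
    parts = []
    for chrom in signal.grid.chroms:
        sl = signal.grid.chrom_slice(chrom)
        obs = el[sl]
        if obs.shape[0] < 2:
            warnings.warn(f"chromosome {chrom} has <2 windows; skipped")
            continue
        trained = baum_welch_train(obs, init, tol=tol, max_iter=max_iter).relabel_by_ratio()
        models[chrom] = trained
        path = viterbi_decode(obs, trained)
        path = merge_short_runs(path, min_run=min_run)
        gamma = posteriors(obs, trained)
        parts.append(states_to_domains(path, chrom, signal.grid, trained, gamma))
    intervals = pd.concat(parts, ignore_index=True)
    params = {c: m.to_dict() for c, m in models.items()}
    return DomainSet(intervals=intervals, sample=sample, model_params=params), models
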