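"""Four-state Gaussian HMM segmentation of binned H3K9me2 coverage.

The model is fitted by Baum-Welch on log1p-transformed bin values, with each
chromosome treated as an independent observation sequence. The four states
are interpreted, in ascending order of emission mean, as background signal,
intermediate-density domains (class 1), high-density domains (class 2) and
aberrantly high artifact ("blacklist") regions. Decoding is Viterbi by
default; posterior (per-bin argmax) decoding is available as an alternative.

Coverage cannot go below zero, so empty bins pile up at exactly 0 and a
plain Gaussian fit overestimates the background mean. Emissions are
therefore modelled as Gaussians left-censored at zero by default: an
observation at 0 contributes the mass Phi((0 - mu)/sd) to the likelihood
and its conditional truncated moments to the M-step (a Tobit-style EM,
still monotone in the observed-data log-likelihood). ``censored=False``
gives the plain Gaussian HMM.

All recursions use the scaled forward/backward formulation, so sequences of
arbitrary length are handled without underflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr

from .intervals import CLASS1, CLASS2, DomainSet
from .layout import GenomeLayout
from .tracks import BinnedTrack

BACKGROUND = "background"
BLACKLIST = "blacklist"
#: class names in ascending order of emission mean
CLASS_ORDER = (BACKGROUND, CLASS1, CLASS2, BLACKLIST)

SD_FLOOR = 1e-3
_INIT_PERCENTILES = (20.0, 50.0, 80.0, 99.5)
_INIT_SELF_TRANSITION = 0.95


class DegenerateInputError(ValueError):
    """Raised when the data cannot support the requested number of states."""


@dataclass
class HmmModel:
    """Fitted HMM: initial distribution, transitions, Gaussian emissions.

    Emission parameters are on the log1p-transformed signal scale.
    """

    initial: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    censored: bool = True
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def n_states(self) -> int:
        return len(self.means)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        k = self.n_states
        if self.transition.shape != (k, k) or len(self.initial) != k or len(self.sds) != k:
            raise ValueError("inconsistent parameter shapes")
        if abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if (self.sds < SD_FLOOR - 1e-12).any():
            raise ValueError(f"emission sds must be >= {SD_FLOOR}")

    def to_json(self, path) -> None:
        payload = {
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "censored": self.censored,
            "loglik_trace": list(map(float, self.loglik_trace)),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HmmModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["initial"]), np.array(d["transition"]),
                   np.array(d["means"]), np.array(d["sds"]),
                   d.get("censored", True),
                   d.get("loglik_trace", []), d.get("n_iter", 0),
                   d.get("converged", False))


@dataclass(frozen=True)
class StateLabeling:
    """Bijection between HMM state indices and domain classes."""

    state_to_class: dict[int, str]

    @property
    def class_to_state(self) -> dict[str, int]:
        return {c: s for s, c in self.state_to_class.items()}


@dataclass(frozen=True)
class StatePath:
    """Decoded per-chromosome state indices at a given bin size."""

    states: dict[str, np.ndarray]
    bin_size: int


# ---------------------------------------------------------------------------
# recursions

def _emission_logprob(x: np.ndarray, means: np.ndarray, sds: np.ndarray,
                      censored: bool = False) -> np.ndarray:
    var = sds**2
    out = -0.5 * (np.log(2 * np.pi * var) + (x[:, None] - means) ** 2 / var)
    if censored:
        at_floor = x <= 0
        if at_floor.any():
            out[at_floor] = log_ndtr((0.0 - means) / sds)
    return out


def _truncated_moments(means: np.ndarray, sds: np.ndarray):
    """E[Z] and E[Z^2] of N(mu, sd^2) truncated to z <= 0, per state."""
    beta = (0.0 - means) / sds
    # lambda = pdf/cdf, computed in log space for stability in far tails
    log_pdf = -0.5 * (np.log(2 * np.pi) + beta**2)
    lam = np.exp(log_pdf - log_ndtr(beta))
    m1 = means - sds * lam
    var = sds**2 * (1.0 - beta * lam - lam**2)
    return m1, np.maximum(var, 0.0) + m1**2


def _forward_backward(logB, pi, A):
    """Scaled forward/backward pass.

    Returns (loglik, gamma, xi_sum) where gamma is the (T, K) posterior and
    xi_sum the (K, K) expected transition counts summed over t.
    """
    T, K = logB.shape
    off = logB.max(axis=1)
    B = np.exp(logB - off[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    loglik = float(np.log(c).sum() + off.sum())
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        W = B[1:] * beta[1:] / c[1:, None]
        xi_sum = A * (alpha[:-1].T @ W)
    else:
        xi_sum = np.zeros((K, K))
    return loglik, gamma, xi_sum


def forward_loglik(model: HmmModel, sequence: np.ndarray) -> float:
    """Log total observation probability via the scaled forward recursion.

    ``sequence`` is on the transformed (log1p) scale.
    """
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("sequence must be a non-empty 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("sequence must be finite")
    logB = _emission_logprob(x, model.means, model.sds, model.censored)
    off = logB.max(axis=1)
    B = np.exp(logB - off[:, None])
    a = model.initial * B[0]
    total = np.log(a.sum())
    a /= a.sum()
    for t in range(1, len(x)):
        a = (a @ model.transition) * B[t]
        total += np.log(a.sum())
        a /= a.sum()
    return float(total + off.sum())


def _viterbi(logB, pi, A):
    T, K = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(A)
        logpi = np.log(pi)
    delta = logpi + logB[0]
    psi = np.empty((T, K), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, None] + logA
        # argmax over rows; np.argmax returns the first (lowest-index) maximum,
        # implementing the stated tie-break
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int32)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# fitting

def transform(values: np.ndarray) -> np.ndarray:
    """Signal transform applied before HMM fitting (log1p)."""
    return np.log1p(values)


def _init_params(x, n_states, rng, jitter):
    if n_states == 4:
        means = np.percentile(x, _INIT_PERCENTILES)
    else:
        qs = np.linspace(10, 90, n_states)
        means = np.percentile(x, qs)
    sd = max(float(np.std(x)), SD_FLOOR)
    means = means.astype(float)
    if jitter:
        means = means + rng.normal(0.0, 0.1 * sd, size=n_states)
        means.sort()
    sds = np.full(n_states, sd)
    pi = np.full(n_states, 1.0 / n_states)
    A = np.full((n_states, n_states),
                (1 - _INIT_SELF_TRANSITION) / (n_states - 1) if n_states > 1 else 0.0)
    np.fill_diagonal(A, _INIT_SELF_TRANSITION if n_states > 1 else 1.0)
    return pi, A, means, sds


def _baum_welch(seqs, pi, A, means, sds, max_iter, tol, censored):
    K = len(means)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(max_iter):
        ll_total = 0.0
        xi_acc = np.zeros((K, K))
        g0_acc = np.zeros(K)
        gsum = np.zeros(K)
        gx = np.zeros(K)
        gxx = np.zeros(K)
        if censored:
            m1, m2 = _truncated_moments(means, sds)
        for x in seqs:
            logB = _emission_logprob(x, means, sds, censored)
            ll, gamma, xi_sum = _forward_backward(logB, pi, A)
            ll_total += ll
            xi_acc += xi_sum
            g0_acc += gamma[0]
            gsum += gamma.sum(axis=0)
            if censored:
                floor = x <= 0
                gx += gamma[~floor].T @ x[~floor] + gamma[floor].sum(axis=0) * m1
                gxx += gamma[~floor].T @ (x[~floor] ** 2) \
                    + gamma[floor].sum(axis=0) * m2
            else:
                gx += gamma.T @ x
                gxx += gamma.T @ (x * x)
        if trace and ll_total < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"Baum-Welch log-likelihood decreased: {trace[-1]} -> {ll_total}")
        trace.append(ll_total)
        n_iter = it + 1
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # M-step
        pi = g0_acc / g0_acc.sum()
        row = xi_acc.sum(axis=1, keepdims=True)
        A = np.where(row > 0, xi_acc / np.maximum(row, 1e-300), A)
        A /= A.sum(axis=1, keepdims=True)
        means = gx / gsum
        var = gxx / gsum - means**2
        sds = np.sqrt(np.maximum(var, SD_FLOOR**2))
    return pi, A, means, sds, trace, n_iter, converged


def fit_hmm(track: BinnedTrack, n_states: int = 4, seed: int = 0,
            max_iter: int = 100, tol: float = 1e-2,
            n_restarts: int = 3, censored: bool = True) -> HmmModel:
    """Fit a Gaussian HMM to the log1p-transformed track by Baum-Welch.

    Each chromosome is an independent observation sequence. Emission means
    are initialized at signal percentiles (20/50/80/99.5 for 4 states) with
    a sticky transition prior; ``n_restarts`` seeded restarts jitter the
    means and the best-likelihood fit is returned. ``censored`` (default)
    treats observations at exactly 0 as left-censored Gaussian mass, which
    removes the upward background-mean bias the zero floor of coverage
    would otherwise cause. Non-convergence within ``max_iter`` returns the
    model with ``converged=False`` and a warning.
    """
    seqs = [transform(track.values[c]) for c in track.layout.names]
    all_x = np.concatenate(seqs)
    if len(np.unique(all_x)) < n_states:
        raise DegenerateInputError(
            f"track has fewer than {n_states} distinct transformed values")
    rng = np.random.default_rng(seed)
    best: HmmModel | None = None
    for restart in range(max(1, n_restarts)):
        pi, A, means, sds = _init_params(all_x, n_states, rng, jitter=restart > 0)
        pi, A, means, sds, trace, n_iter, converged = _baum_welch(
            seqs, pi, A, means, sds, max_iter, tol, censored)
        model = HmmModel(pi, A, means, sds, censored, trace, n_iter, converged)
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    if not best.converged:
        warnings.warn("Baum-Welch did not converge within max_iter", RuntimeWarning)
    return best


# ---------------------------------------------------------------------------
# decoding and segmentation

def decode_states(model: HmmModel, track: BinnedTrack,
                  method: str = "viterbi") -> StatePath:
    """Decode a per-chromosome state path (Viterbi or posterior argmax)."""
    if method not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decode method {method!r}")
    states = {}
    for chrom in track.layout.names:
        x = transform(track.values[chrom])
        logB = _emission_logprob(x, model.means, model.sds, model.censored)
        if method == "viterbi":
            states[chrom] = _viterbi(logB, model.initial, model.transition)
        else:
            _, gamma, _ = _forward_backward(logB, model.initial, model.transition)
            states[chrom] = np.argmax(gamma, axis=1).astype(np.int32)
    return StatePath(states, track.bin_size)


def state_posteriors(model: HmmModel, track: BinnedTrack) -> dict[str, np.ndarray]:
    """Per-bin posterior state probabilities, one (n_bins, n_states) array
    per chromosome."""
    out = {}
    for chrom in track.layout.names:
        x = transform(track.values[chrom])
        logB = _emission_logprob(x, model.means, model.sds, model.censored)
        _, gamma, _ = _forward_backward(logB, model.initial, model.transition)
        out[chrom] = gamma
    return out


def write_posteriors_tsv(posteriors: dict[str, np.ndarray], bin_size: int, path) -> None:
    """Write per-bin posteriors as TSV (chrom, start, p_state0..p_stateK)."""
    with open(path, "w") as fh:
        k = next(iter(posteriors.values())).shape[1]
        header = "\t".join(["chrom", "start"] + [f"p_state{i}" for i in range(k)])
        fh.write(header + "\n")
        for chrom, gamma in posteriors.items():
            for i, row in enumerate(gamma):
                vals = "\t".join(f"{p:.6g}" for p in row)
                fh.write(f"{chrom}\t{i * bin_size}\t{vals}\n")


def label_states(model: HmmModel) -> StateLabeling:
    """Label states by ascending emission mean: background, class1, class2, blacklist.

    Tied means are broken by smaller sd, then by state index, with a warning.
    """
    if model.n_states != len(CLASS_ORDER):
        raise ValueError(f"labeling requires {len(CLASS_ORDER)} states")
    if len(np.unique(model.means)) < model.n_states:
        warnings.warn("tied emission means; tie-break by sd then state index",
                      RuntimeWarning)
    order = sorted(range(model.n_states),
                   key=lambda i: (model.means[i], model.sds[i], i))
    return StateLabeling({int(s): CLASS_ORDER[rank] for rank, s in enumerate(order)})


def segment_domains(path: StatePath, labeling: StateLabeling,
                    layout: GenomeLayout, min_domain_bins: int = 1,
                    max_gap_bins: int = 0) -> DomainSet:
    """Turn maximal class1/class2 state runs into classified intervals.

    Background and blacklist bins are excluded (a blacklist bin therefore
    splits a domain). Runs shorter than ``min_domain_bins`` are dropped;
    same-class runs separated by at most ``max_gap_bins`` non-domain bins
    are merged when ``max_gap_bins`` > 0.
    """
    bin_size = path.bin_size
    records = []
    for chrom, states in path.states.items():
        classes = np.array([labeling.state_to_class[int(s)] for s in states])
        runs = _runs(classes)
        if max_gap_bins > 0:
            runs = _merge_gaps(runs, max_gap_bins)
        runs = [r for r in runs if r[2] in (CLASS1, CLASS2)]
        for start_bin, end_bin, klass in runs:
            if end_bin - start_bin < min_domain_bins:
                continue
            start = start_bin * bin_size
            end = min(end_bin * bin_size, layout.length(chrom))
            records.append((chrom, start, end, klass))
    if not records:
        return DomainSet.empty()
    return DomainSet.from_records(records)


def _runs(classes: np.ndarray) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            runs.append((start, i, str(classes[start])))
            start = i
    return runs


def _merge_gaps(runs, max_gap_bins):
    """Merge same-class domain runs separated only by short non-domain runs.

    Operates on the full run list (all classes) so that an intervening
    domain run of the other class is never bridged.
    """
    merged: list[list] = [list(r) for r in runs]
    out: list[list] = []
    i = 0
    while i < len(merged):
        run = merged[i]
        if run[2] not in (CLASS1, CLASS2):
            out.append(run)
            i += 1
            continue
        # try to extend across a single non-domain gap to a same-class run
        if (i + 2 < len(merged)
                and merged[i + 1][2] not in (CLASS1, CLASS2)
                and merged[i + 2][2] == run[2]
                and merged[i + 1][1] - merged[i + 1][0] <= max_gap_bins):
            merged[i + 2][0] = run[0]
            i += 2
            continue
        out.append(run)
        i += 1
    return [tuple(r) for r in out]
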