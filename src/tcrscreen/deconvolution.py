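"""Mixture-of-PWMs motif deconvolution with a fixed flat background.

One round of panning leaves a substantial fraction of non-specific sequences
in the output library. Per core length L, the model explains each core
``s`` as a mixture of ``k`` position-weight-matrix motifs plus one *flat*
component pinned to the input-library amino-acid composition::

    p(s) = w_flat * prod_p b(s_p)  +  sum_m w_m * prod_p f_{m,p}(s_p)

Fitted by EM (background frequencies never updated), with random restarts.
Cores assigned to the flat component, or to motifs with no position whose
information content (KL divergence to the background, in bits) exceeds the
gate, are reported as putative contaminants; the rest are binders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .alphabet import AMINO_ACIDS, seq_to_indices
from .processing import CoreSet


@dataclass
class BackgroundFreqs:
    """Position-pooled amino-acid composition of the input library."""

    freqs: np.ndarray  # length 20, strictly positive after smoothing
    pseudocount: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (20,):
            raise ValueError("background must be a length-20 frequency vector")
        if abs(self.freqs.sum() - 1.0) > 1e-9 or np.any(self.freqs < 0):
            raise ValueError("background frequencies must form a distribution")


@dataclass
class MixtureModel:
    """Fitted mixture: k motif PWMs + the fixed flat component.

    ``weights`` has length k+1 with the flat component last;
    ``responsibilities`` is (n_sequences, k+1) in the same order.
    """

    pwms: list[np.ndarray]
    weights: np.ndarray
    background: BackgroundFreqs
    responsibilities: np.ndarray
    log_likelihood: float
    trace: list[float] = field(default_factory=list)
    pseudocount: float = 0.1

    @property
    def k(self) -> int:
        return len(self.pwms)


@dataclass
class DeconvolutionResult:
    """Binder/contaminant partition of one length class, with its motif."""

    length: int
    binders: list[str]
    contaminants: list[str]
    pwm: np.ndarray
    information_content: np.ndarray
    ic_pass: bool
    model: MixtureModel


def estimate_background(input_cores: CoreSet, pseudocount: float = 0.5) -> BackgroundFreqs:
    """Pool amino-acid counts over all positions of all input cores.

    Additive smoothing keeps every frequency strictly positive so that
    likelihood ratios and information content stay finite.
    """
    counts = np.zeros(20)
    n_letters = 0
    for core in input_cores.all_cores():
        idx = seq_to_indices(core)
        np.add.at(counts, idx, 1.0)
        n_letters += len(idx)
    if n_letters == 0:
        raise ValueError("input core set is empty; cannot estimate background")
    smoothed = counts + pseudocount
    return BackgroundFreqs(freqs=smoothed / smoothed.sum(), pseudocount=pseudocount)


def _encode(cores: list[str]) -> np.ndarray:
    lengths = {len(c) for c in cores}
    if len(lengths) != 1:
        raise ValueError(f"cores must share one length, got lengths {sorted(lengths)}")
    return np.stack([seq_to_indices(c) for c in cores])


def _motif_loglik(X: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    logf = np.log(pwm)
    return logf[np.arange(X.shape[1])[None, :], X].sum(axis=1)


def fit_mixture(
    cores: list[str],
    k: int,
    background: BackgroundFreqs,
    *,
    pseudocount: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> MixtureModel:
    """Fit the k-motif + flat-background mixture by EM, best of restarts.

    Parameters
    ----------
    cores
        Equal-length core sequences (one length class).
    k
        Number of motif components beside the fixed flat one (default 1 in
        the screening workflow).
    background
        Flat-component frequencies, estimated from the input library and
        never updated during EM.
    pseudocount
        Additive smoothing on PWM rows at every M-step; keeps entries > 0.
    tol
        Relative log-likelihood change declaring convergence.

    Returns the restart with the highest final log-likelihood; the trace of
    that run is non-decreasing (EM ascent property, asserted in tests).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cores) < k + 1:
        raise ValueError(
            f"need at least k+1={k + 1} sequences to fit {k} motifs + background, "
            f"got {len(cores)}"
        )
    X = _encode(cores)
    n, L = X.shape
    bg_ll = np.log(background.freqs)[X].sum(axis=1)  # fixed component
    rng = np.random.default_rng(seed)

    best: MixtureModel | None = None
    for _ in range(n_restarts):
        # init PWMs by perturbing empirical position frequencies
        pwms = []
        for _m in range(k):
            counts = np.zeros((L, 20))
            for p in range(L):
                np.add.at(counts[p], X[:, p], 1.0)
            noise = rng.dirichlet(np.ones(20), size=L)
            f = counts / counts.sum(axis=1, keepdims=True)
            f = 0.5 * f + 0.5 * noise
            pwms.append(f / f.sum(axis=1, keepdims=True))
        weights = np.full(k + 1, 1.0 / (k + 1))

        trace: list[float] = []
        resp = np.zeros((n, k + 1))
        for _it in range(max_iter):
            # E-step
            comp_ll = np.empty((n, k + 1))
            for m in range(k):
                comp_ll[:, m] = _motif_loglik(X, pwms[m])
            comp_ll[:, k] = bg_ll
            joint = comp_ll + np.log(weights)
            norm = logsumexp(joint, axis=1)
            resp = np.exp(joint - norm[:, None])
            ll = float(norm.sum())
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
                break
            # M-step (flat component frequencies stay fixed)
            weights = resp.mean(axis=0)
            weights = np.clip(weights, 1e-12, None)
            weights /= weights.sum()
            for m in range(k):
                counts = np.full((L, 20), pseudocount)
                for p in range(L):
                    np.add.at(counts[p], X[:, p], resp[:, m])
                pwms[m] = counts / counts.sum(axis=1, keepdims=True)
        model = MixtureModel(
            pwms=pwms,
            weights=weights,
            background=background,
            responsibilities=resp,
            log_likelihood=trace[-1],
            trace=trace,
            pseudocount=pseudocount,
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    return best


def position_information_content(
    pwm: np.ndarray, background: BackgroundFreqs
) -> np.ndarray:
    """Per-position KL divergence of the motif to the background, in bits.

    ``IC_p = sum_a f_{p,a} * log2(f_{p,a} / b_a)``; non-negative whenever the
    rows of ``pwm`` are probability vectors.
    """
    pwm = np.asarray(pwm, dtype=float)
    b = background.freqs
    if np.any(b <= 0):
        raise ValueError("background has zero entries; smooth it before computing IC")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pwm > 0, pwm * np.log2(pwm / b), 0.0)
    return terms.sum(axis=1)


def classify_binders(
    model: MixtureModel,
    cores: list[str],
    ic_threshold: float = 1.0,
) -> DeconvolutionResult:
    """Assign cores to components and gate motifs on information content.

    Each core goes to its maximum-responsibility component (ties assigned to
    the flat component — conservative, favors contaminant). Cores in the
    flat component, or in a motif with no position of IC above
    ``ic_threshold`` bits, are contaminants; the rest are binders.
    """
    if len(cores) != model.responsibilities.shape[0]:
        raise ValueError("cores do not match the fitted responsibilities")
    k = model.k
    resp = model.responsibilities
    flat_resp = resp[:, k]
    motif_best = resp[:, :k].argmax(axis=1)
    motif_resp = resp[np.arange(len(cores)), motif_best]
    # ties go to the flat component
    in_flat = flat_resp >= motif_resp
    ic = [position_information_content(pwm, model.background) for pwm in model.pwms]
    motif_passes = np.array([float(v.max()) > ic_threshold for v in ic])

    binders, contaminants = [], []
    for i, core in enumerate(cores):
        if in_flat[i] or not motif_passes[motif_best[i]]:
            contaminants.append(core)
        else:
            binders.append(core)
    main = int(np.bincount(motif_best, minlength=k).argmax())
    return DeconvolutionResult(
        length=len(cores[0]) if cores else 0,
        binders=binders,
        contaminants=contaminants,
        pwm=model.pwms[main],
        information_content=ic[main],
        ic_pass=bool(motif_passes[main]),
        model=model,
    )


def deconvolve_cores(
    output_cores: CoreSet,
    background: BackgroundFreqs,
    *,
    k: int = 1,
    ic_threshold: float = 1.0,
    seed: int = 0,
    **fit_opts,
) -> dict[int, DeconvolutionResult]:
    """Run deconvolution independently per core length (fixed-length PWMs)."""
    results: dict[int, DeconvolutionResult] = {}
    for length in sorted(output_cores.cores):
        cores = output_cores.cores[length]
        if len(cores) < k + 1:
            continue
        model = fit_mixture(cores, k, background, seed=seed + length, **fit_opts)
        results[length] = classify_binders(model, cores, ic_threshold=ic_threshold)
    return results


def pwm_to_frame(pwm: np.ndarray) -> pd.DataFrame:
    """Logo-ready position-frequency matrix (rows = positions, cols = residues)."""
    return pd.DataFrame(np.asarray(pwm), columns=list(AMINO_ACIDS))
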