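"""Ungapped motif discovery by expectation-maximization under a ZOOPS model.

ZOOPS ("zero or one occurrence per sequence") assumes each input sequence
either contains exactly one motif site — at an unknown offset, on either
strand — with probability gamma, or is pure background.  EM alternates
between soft site assignment (E-step) and matrix/gamma re-estimation
(M-step).  An optional palindromic constraint averages the matrix with its
own reverse complement after every M-step, the appropriate model for dyad
sites bound by homodimers.

Discovery is restarted from several data-derived seedings and the run with
the best final log-likelihood wins; with short randomized cores the
likelihood surface is multimodal and a single start routinely locks onto a
shifted alignment.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .pwm import _SET_TO_CODE, ConsensusPattern, PWMotif
from .seqs import composition, encode_many


class ZoopsMotifEM(BaseEstimator):
    """ZOOPS EM motif estimator over fixed-length DNA sequences.

    Parameters
    ----------
    width:
        Motif width (positions in the letter-probability matrix).
    palindromic:
        If True, constrain the matrix to be self-reverse-complementary by
        averaging it with its reverse complement after each M-step.
    n_starts:
        Number of EM restarts; each is seeded from a randomly chosen
        width-length subsequence (either strand) of the input.
    max_iter, tol:
        Convergence control: stop when the log-likelihood improves by less
        than ``tol`` or after ``max_iter`` iterations.
    pseudocount:
        Dirichlet pseudocount added per base per position in the M-step.
    random_state:
        Seed for restart initialisation.

    Attributes
    ----------
    pwm_ : PWMotif
        Fitted motif (best restart), background set to the input 0-order
        composition and ``score_significance`` to the log-likelihood-ratio
        versus the background-only model.
    log_likelihood_ : float
        Final log-likelihood of the best restart.
    log_likelihood_trace_ : np.ndarray
        Per-iteration log-likelihoods of the best restart.
    gamma_ : float
        Fitted prior probability that a sequence contains a site.
    nsites_ : int
        Rounded expected number of site-containing sequences.
    """

    def __init__(
        self,
        width: int = 20,
        palindromic: bool = False,
        n_starts: int = 20,
        max_iter: int = 200,
        tol: float = 1e-3,
        pseudocount: float = 0.1,
        random_state: int | None = None,
    ):
        self.width = width
        self.palindromic = palindromic
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.pseudocount = pseudocount
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------

    def _windows(self, X: np.ndarray) -> np.ndarray:
        """All site placements: forward windows then reverse-complement windows.

        Returns an int array of shape (n, 2*(L-w+1), w) whose entries are
        already in motif orientation (RC placements complemented+reversed),
        so M-step counts accumulate directly.
        """
        w = self.width
        fwd = sliding_window_view(X, w, axis=1)  # (n, L-w+1, w)
        rc = (3 - fwd)[:, :, ::-1]
        return np.concatenate([fwd, rc], axis=1)

    def _em_run(self, wins, log_bg_seq, bg, rng):
        n, n_place, w = wins.shape
        # Seed the matrix from one randomly chosen placement.
        seed_win = wins[rng.integers(n), rng.integers(n_place)]
        matrix = np.full((w, 4), 0.16)
        matrix[np.arange(w), seed_win] = 0.52
        if self.palindromic:
            matrix = 0.5 * (matrix + matrix[::-1, ::-1])
        gamma = 0.5
        log_bg_win = np.log(bg)[wins].sum(axis=2)  # (n, n_place), constant
        trace = []
        prev_ll = -np.inf
        for _ in range(self.max_iter):
            # E-step: posterior placement responsibilities.
            log_ratio = np.log(matrix)[np.arange(w), wins].sum(axis=2) - log_bg_win
            r = np.exp(log_ratio)  # motif/background likelihood ratio per placement
            site_term = (gamma / n_place) * r.sum(axis=1)
            denom = (1.0 - gamma) + site_term
            ll = float(log_bg_seq.sum() + np.log(denom).sum())
            trace.append(ll)
            if ll - prev_ll < self.tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
            z = (gamma / n_place) * r / denom[:, None]  # (n, n_place)
            # M-step.
            zw = z.ravel()
            counts = np.empty((w, 4))
            for k in range(w):
                counts[k] = np.bincount(wins[:, :, k].ravel(), weights=zw, minlength=4)
            counts += self.pseudocount
            matrix = counts / counts.sum(axis=1, keepdims=True)
            if self.palindromic:
                matrix = 0.5 * (matrix + matrix[::-1, ::-1])
            gamma = float(np.clip(z.sum(axis=1).mean(), 1e-6, 1.0 - 1e-6))
        q = z.sum(axis=1)
        return matrix, gamma, np.array(trace), q

    # -- sklearn-style API -------------------------------------------------

    def fit(self, X, y=None):
        """Fit the motif model.  ``X`` is a sequence of equal-length DNA strings."""
        seqs = list(X)
        if not seqs:
            raise ValueError("empty input: no sequences to fit")
        if min(len(s) for s in seqs) < self.width:
            raise ValueError(
                f"motif width {self.width} exceeds shortest sequence "
                f"({min(len(s) for s in seqs)} nt)"
            )
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        enc = encode_many(seqs)
        bg = composition(seqs)
        self.background_ = bg
        log_bg_seq = np.log(bg)[enc].sum(axis=1)  # (n,)
        wins = self._windows(enc)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_starts):
            matrix, gamma, trace, q = self._em_run(wins, log_bg_seq, bg, rng)
            if best is None or trace[-1] > best[2][-1]:
                best = (matrix, gamma, trace, q)
        matrix, gamma, trace, q = best
        self.gamma_ = gamma
        self.log_likelihood_ = float(trace[-1])
        self.log_likelihood_trace_ = trace
        self.n_iter_ = len(trace)
        self.nsites_ = int(round(q.sum()))
        llr = self.log_likelihood_ - float(log_bg_seq.sum())
        self.pwm_ = PWMotif(
            matrix=matrix,
            background=bg,
            nsites=self.nsites_,
            score_significance=llr,
        )
        return self

    def score(self, X, y=None) -> float:
        """Per-sequence average log-likelihood under the fitted model."""
        seqs = list(X)
        enc = encode_many(seqs)
        bg = self.background_
        log_bg_seq = np.log(bg)[enc].sum(axis=1)
        wins = self._windows(enc)
        w = self.width
        log_bg_win = np.log(bg)[wins].sum(axis=2)
        log_ratio = np.log(self.pwm_.matrix)[np.arange(w), wins].sum(axis=2) - log_bg_win
        site_term = (self.gamma_ / wins.shape[1]) * np.exp(log_ratio).sum(axis=1)
        return float((log_bg_seq + np.log((1 - self.gamma_) + site_term)).mean())


def discover_motif(
    cores,
    width: int = 20,
    palindromic: bool = False,
    n_starts: int = 20,
    max_iter: int = 200,
    tol: float = 1e-3,
    seed: int | None = None,
    sample: int | None = None,
) -> PWMotif:
    """Discover the best ungapped motif in a set of DNA cores.

    ``sample`` optionally subsamples the input (without replacement, seeded)
    before discovery, the usual practice when refined selection libraries run
    to tens of thousands of reads.
    """
    cores = list(cores)
    if sample is not None and sample < len(cores):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(cores), size=sample, replace=False)
        cores = [cores[i] for i in idx]
    est = ZoopsMotifEM(
        width=width,
        palindromic=palindromic,
        n_starts=n_starts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    est.fit(cores)
    return est.pwm_


def consensus_from_pwm(
    pwm: PWMotif, single_threshold: float = 0.8, pair_threshold: float = 0.8
) -> ConsensusPattern:
    """Reduce a matrix to an IUPAC consensus with dyad structure.

    Per position: the top base if its probability reaches ``single_threshold``;
    else the two top bases' degenerate code if their sum reaches
    ``pair_threshold``; else N.
    """
    if not (0 < single_threshold <= 1 and 0 < pair_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    if single_threshold < pair_threshold / 2:
        raise ValueError("single_threshold must be >= pair_threshold / 2")
    letters = []
    for row in pwm.matrix:
        order = np.argsort(row)[::-1]
        if row[order[0]] >= single_threshold:
            letters.append("ACGT"[order[0]])
        elif row[order[0]] + row[order[1]] >= pair_threshold:
            pair = frozenset("ACGT"[i] for i in order[:2])
            letters.append(_SET_TO_CODE[pair])
        else:
            letters.append("N")
    return ConsensusPattern.from_iupac("".join(letters))


def information_content(pwm: PWMotif) -> np.ndarray:
    """Per-position information content in bits against a uniform background.

    IC_i = 2 + sum_b p_ib log2 p_ib, with 0*log(0) = 0; total IC is the sum.
    """
    p = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)
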