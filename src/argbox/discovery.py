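"""Palindrome-constrained EM motif discovery over probe sequence sets.

Finds an ungapped motif of width w in a set of probe sequences with a
two-component mixture: windows are either draws from a position frequency
matrix (on either strand) or from a 0-order background.  Two occurrence
models are supported:

* ``zoops`` — zero or one occurrence per sequence, with a sequence-level
  site prior gamma re-estimated each iteration;
* ``anr`` — any number of repetitions: every window is independently a site
  with probability lambda, bounded so the expected number of sites per
  sequence stays below a configurable cap (tandem operator boxes motivate a
  default cap of 2).

``discriminative=True`` estimates the background from a supplied negative
set instead of from the positives, sharpening discovery when binding and
non-binding probes are available.  ``palindrome=True`` constrains the motif
to strand symmetry: the M-step averages the expected count matrix with its
reverse-complement mirror, which is the exact maximizer within the
symmetric family, so EM monotonicity is preserved.

The M-step adds a small Dirichlet pseudocount for numerical stability, so
the monotone objective reported in ``objective_trace`` is the penalized
(MAP) log-likelihood.  Width selection across the configured range uses the
final log-likelihood ratio against the background-only model, penalized by
the parameter count (3 free frequencies per column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .iimodel import PositionFrequencyMatrix, build_pfm
from .seqio import NucleotideSequence, reverse_complement

__all__ = [
    "MotifSearchConfig",
    "DiscoveredMotif",
    "em_discover",
    "site_calls_to_alignment",
]

logger = logging.getLogger("argbox.discovery")


@dataclass(frozen=True)
class MotifSearchConfig:
    width_min: int = 14
    width_max: int = 20
    mode: str = "zoops"                  # "zoops" | "anr"
    discriminative: bool = False
    palindrome: bool = True
    max_iter: int = 200
    tol: float = 1e-6                    # convergence threshold on the objective
    seed: int = 0
    n_starts: int = 10
    anr_max_sites_per_seq: float = 2.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if not (1 <= self.width_min <= self.width_max):
            raise ValueError("need 1 <= width_min <= width_max")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        if self.mode not in {"zoops", "anr"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class DiscoveredMotif:
    pfm: PositionFrequencyMatrix
    width: int
    site_calls: list[tuple[str, int, str, float]]  # (seq id, offset, strand, posterior)
    log_likelihood_ratio: float
    objective_trace: list[float]
    width_scores: dict[int, float]
    converged: bool

    def consensus(self) -> str:
        from .seqio import ALPHABET

        f = self.pfm.frequencies
        return "".join(ALPHABET[i] for i in np.argmax(f, axis=0))


def _encode_all(seqs: list[NucleotideSequence]) -> list[np.ndarray]:
    from .iimodel import encode

    return [encode(s.residues) for s in seqs]


def _composition(codes: list[np.ndarray]) -> np.ndarray:
    counts = np.zeros(4)
    for c in codes:
        counts += np.bincount(c, minlength=4)
    return counts / counts.sum()


def _window_matrix(codes: np.ndarray, w: int) -> np.ndarray:
    """All length-w windows of one sequence as an (m, w) integer matrix."""
    m = len(codes) - w + 1
    idx = np.arange(w)[None, :] + np.arange(m)[:, None]
    return codes[idx]


class _WidthEM:
    """One EM problem at fixed width; holds precomputed windows."""

    def __init__(self, codes, seq_ids, w, q, cfg: MotifSearchConfig):
        self.w = w
        self.q = q
        self.cfg = cfg
        self.seq_ids = seq_ids
        self.windows = []        # per sequence: (m, w) forward windows
        self.logq_win = []       # per sequence: (m,) background log-prob of window
        logq = np.log(q)
        for c in codes:
            if len(c) < w:
                raise ValueError(f"sequence shorter than motif width {w}")
            wm = _window_matrix(c, w)
            self.windows.append(wm)
            self.logq_win.append(logq[wm].sum(axis=1))
        self.n_seq = len(codes)
        self.total_windows = sum(len(w_) for w_ in self.windows)

    # -- model helpers -----------------------------------------------------

    def _log_ratio(self, f: np.ndarray, wm: np.ndarray, logq_win: np.ndarray):
        """log LR of each (window, strand): motif vs background.  Returns
        (2m,) with forward windows first, then reverse-strand ones."""
        logf = np.log(f)
        fwd = logf[wm, np.arange(self.w)].sum(axis=1) - logq_win
        rev = logf[::-1, ::-1][wm, np.arange(self.w)].sum(axis=1) - logq_win
        return np.concatenate([fwd, rev])

    def _counts_from_posteriors(self, z_all) -> np.ndarray:
        counts = np.zeros((4, self.w))
        cols = np.arange(self.w)
        for wm, z in zip(self.windows, z_all):
            m = len(wm)
            zf, zr = z[:m], z[m:]
            kf = zf > 1e-12
            if kf.any():
                np.add.at(
                    counts,
                    (wm[kf].ravel(), np.tile(cols, int(kf.sum()))),
                    np.repeat(zf[kf], self.w),
                )
            kr = zr > 1e-12
            if kr.any():
                rc = 3 - wm[kr][:, ::-1]
                np.add.at(
                    counts,
                    (rc.ravel(), np.tile(cols, int(kr.sum()))),
                    np.repeat(zr[kr], self.w),
                )
        return counts

    def _m_step(self, z_all) -> np.ndarray:
        counts = self._counts_from_posteriors(z_all) + self.cfg.pseudocount
        if self.cfg.palindrome:
            counts = 0.5 * (counts + counts[::-1, ::-1])
        return counts / counts.sum(axis=0, keepdims=True)

    def _objective_prior(self, f: np.ndarray) -> float:
        return float(self.cfg.pseudocount * np.log(f).sum())

    # -- occurrence models -------------------------------------------------

    def run(self, f0: np.ndarray):
        zoops = self.cfg.mode == "zoops"
        f = f0.copy()
        gamma = 0.5  # zoops: P(sequence has a site); anr: per-window site prob
        if not zoops:
            gamma = min(0.5, self.cfg.anr_max_sites_per_seq * self.n_seq / self.total_windows)
        trace: list[float] = []
        converged = False
        for _ in range(self.cfg.max_iter):
            z_all, loglik, site_post = self._e_step(f, gamma)
            obj = loglik + self._objective_prior(f)
            if trace and obj < trace[-1] - 1e-9:
                logger.warning("EM objective decreased by %.3g", trace[-1] - obj)
            trace.append(obj)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < self.cfg.tol:
                converged = True
                break
            f = self._m_step(z_all)
            if zoops:
                gamma = float(np.clip(np.mean(site_post), 1e-6, 1 - 1e-6))
            else:
                cap = self.cfg.anr_max_sites_per_seq * self.n_seq / self.total_windows
                z_mean = np.mean(np.concatenate(z_all))
                gamma = float(np.clip(z_mean, 1e-9, min(cap, 1 - 1e-9)))
        if not converged:
            # refresh posteriors so calls and likelihood match the final matrix
            z_all, loglik, site_post = self._e_step(f, gamma)
            trace.append(loglik + self._objective_prior(f))
        _, loglik0, _ = self._e_step(f, 0.0 if zoops else 1e-300)
        return f, gamma, trace, loglik - loglik0, z_all, converged

    def _e_step(self, f: np.ndarray, gamma: float):
        z_all, site_post = [], []
        loglik = 0.0
        for wm, logq_win in zip(self.windows, self.logq_win):
            m = len(wm)
            logr = self._log_ratio(f, wm, logq_win)
            bg_ll = float(logq_win.sum())  # full-sequence bg log-lik (windows share it)
            if self.cfg.mode == "zoops":
                if gamma <= 0.0:
                    z = np.zeros(2 * m)
                    loglik += bg_ll
                    z_all.append(z)
                    site_post.append(0.0)
                    continue
                # uniform site-position prior over 2m (offset, strand) choices
                a = np.log(gamma / (2 * m)) + logr
                amax = max(a.max(), 0.0)
                denom = (1 - gamma) * np.exp(-amax) + np.exp(a - amax).sum()
                z = np.exp(a - amax) / denom
                loglik += bg_ll + amax + np.log(denom)
                site_post.append(float(z.sum()))
            else:
                lam = gamma
                lr = np.exp(np.clip(logr, -700, 700))
                denom = (1 - lam) + lam * lr
                z = lam * lr / denom
                loglik += bg_ll + float(np.log(denom).sum())
                site_post.append(float(z.sum()))
            z_all.append(z)
        return z_all, loglik, site_post

    # -- seeding -----------------------------------------------------------

    def seeds(self, rng: np.random.Generator) -> list[np.ndarray]:
        """Deterministic starting matrices plus one random start.

        Candidate windows are pre-ranked by rarity under the background, the
        most promising ones re-scored by how strongly the rest of the data
        matches a smoothed one-hot model of the window, and the top
        ``n_starts`` kept.
        """
        rarity = np.concatenate([-lq for lq in self.logq_win])
        owners = np.concatenate(
            [np.full(len(wm), i) for i, wm in enumerate(self.windows)]
        )
        order = np.argsort(-rarity, kind="stable")
        shortlist = order[: max(10 * self.cfg.n_starts, 50)]
        offsets = np.concatenate([np.arange(len(wm)) for wm in self.windows])
        scored = []
        for cand in shortlist:
            i, j = int(owners[cand]), int(offsets[cand])
            f = self._one_hot(self.windows[i][j])
            score = 0.0
            for wm, logq_win in zip(self.windows, self.logq_win):
                logr = self._log_ratio(f, wm, logq_win)
                score += float(logr.max())
            scored.append((score, i, j))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        starts = [
            self._one_hot(self.windows[i][j]) for _, i, j in scored[: self.cfg.n_starts]
        ]
        random_f = rng.dirichlet(np.ones(4), size=self.w).T
        starts.append(random_f)
        if self.cfg.palindrome:
            starts = [0.5 * (f + f[::-1, ::-1]) for f in starts]
        return starts

    def _one_hot(self, window: np.ndarray, match: float = 0.55) -> np.ndarray:
        f = np.full((4, self.w), (1 - match) / 3)
        f[window, np.arange(self.w)] = match
        return f


def em_discover(
    positives: list[NucleotideSequence],
    negatives: list[NucleotideSequence] | None = None,
    config: MotifSearchConfig = MotifSearchConfig(),
) -> DiscoveredMotif:
    """Discover the best motif over the configured width range.

    Deterministic given ``config.seed``.  Returns the best-width motif with
    its site calls, LLR and per-width model-selection scores.
    """
    if len(positives) < 2:
        raise ValueError("need at least 2 positive sequences")
    if config.discriminative and not negatives:
        raise ValueError("discriminative mode requires a negative set")
    codes = _encode_all(positives)
    min_len = min(len(c) for c in codes)
    if min_len < config.width_max:
        raise ValueError(
            f"sequences of length {min_len} shorter than width_max {config.width_max}"
        )
    if config.discriminative:
        q = _composition(_encode_all(negatives))
    else:
        q = _composition(codes)
    q = np.clip(q, 1e-6, None)
    q = q / q.sum()

    seq_ids = [s.id for s in positives]
    best = None
    width_scores: dict[int, float] = {}
    for w in range(config.width_min, config.width_max + 1):
        rng = np.random.default_rng((config.seed, w))
        em = _WidthEM(codes, seq_ids, w, q, config)
        best_run = None
        for f0 in em.seeds(rng):
            f, gamma, trace, llr, z_all, converged = em.run(f0)
            if best_run is None or trace[-1] > best_run[2][-1]:
                best_run = (f, gamma, trace, llr, z_all, converged)
        f, gamma, trace, llr, z_all, converged = best_run
        score = llr - 3.0 * w  # parameter-count penalty
        width_scores[w] = score
        if not converged:
            logger.warning("EM did not converge at width %d; best-so-far returned", w)
        if best is None or score > best[0]:
            best = (score, w, f, gamma, trace, llr, z_all, converged)

    _, w, f, gamma, trace, llr, z_all, converged = best
    calls = _site_calls(z_all, seq_ids, w, config)
    counts_scale = 1000  # report the EM frequencies as a fixed-precision PFM
    pfm = PositionFrequencyMatrix(
        counts=np.round(f * counts_scale, 6), n=counts_scale
    )
    return DiscoveredMotif(
        pfm=pfm,
        width=w,
        site_calls=calls,
        log_likelihood_ratio=llr,
        objective_trace=trace,
        width_scores=width_scores,
        converged=converged,
    )


def _site_calls(z_all, seq_ids, w, config) -> list[tuple[str, int, str, float]]:
    calls = []
    for sid, z in zip(seq_ids, z_all):
        m = len(z) // 2
        if config.mode == "zoops":
            total = z.sum()
            if total > 0.5:
                c = int(np.argmax(z))
                strand = "+" if c < m else "-"
                calls.append((sid, c % m, strand, float(z[c])))
        else:
            order = np.argsort(-z, kind="stable")
            taken: list[int] = []
            for c in order:
                if z[c] <= 0.5:
                    break
                off = int(c) % m
                if any(abs(off - t) < w for t in taken):
                    continue
                taken.append(off)
                calls.append((sid, off, "+" if c < m else "-", float(z[c])))
    return calls


def site_calls_to_alignment(
    motif: DiscoveredMotif, seqs: list[NucleotideSequence]
) -> list[NucleotideSequence]:
    """Extract called windows (reverse-complemented on '-') as an alignment."""
    by_id = {s.id: s for s in seqs}
    out = []
    for sid, off, strand, _post in motif.site_calls:
        s = by_id[sid]
        if off < 0 or off + motif.width > len(s):
            raise ValueError(f"site call at {sid}:{off} outside sequence bounds")
        window = s.residues[off : off + motif.width]
        if strand == "-":
            window = reverse_complement(window)
        out.append(NucleotideSequence(f"{sid}|{off}|{strand}", window))
    return out
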