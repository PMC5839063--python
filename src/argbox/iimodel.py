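"""Individual-information modelling of binding sites.

This is the package's mathematical core, after Schneider's information-theory
treatment of binding sites.  From an alignment of n site sequences of width L
it derives:

* the position frequency matrix ``f(b, l)``,
* the small-sample entropy correction ``e(n)`` — the expected upward bias of
  the plug-in entropy of n draws from a uniform base distribution, so that a
  random alignment scores ~0 bits,
* per-position observed entropies ``H(l)`` (bits),
* the individual-information weight matrix
  ``Riw(b, l) = 2 + log2 f(b, l) - e(n)`` (bits),
* the model conservation ``Rsequence = sum_l [2 - H(l) - e(n)]`` (bits).

The score of one sequence, ``Ri(s) = sum_l Riw(s_l, l)``, measures in bits how
well it matches the model; by construction the mean Ri over the training
alignment equals Rsequence exactly.

For palindromic operators (such as the ARG box, bound by a symmetric ArgR
oligomer) the model should not depend on which strand of each site happens to
be written down: :func:`build_model_from_sequences` with ``palindromic=True``
pools each training sequence with its reverse complement before counting,
which makes ``f(b, l) = f(complement(b), L + 1 - l)`` hold exactly and scores
each sequence and its reverse complement identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .seqio import ALPHABET, AlphabetError, NucleotideSequence, reverse_complement

__all__ = [
    "PositionFrequencyMatrix",
    "IndividualInformationModel",
    "ScoringError",
    "build_pfm",
    "small_sample_correction",
    "build_model",
    "build_model_from_sequences",
    "ri_score",
    "consensus",
    "logo_data",
    "save_model",
    "load_model",
]

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class ScoringError(ValueError):
    """Sequence cannot be scored under the model (length or alphabet)."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts and frequencies of an aligned site set.

    ``counts`` has shape (4, L) with rows in A, C, G, T order and column sums
    all equal to ``n``.
    """

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A, C, G, T)")
        sums = counts.sum(axis=0)
        if not np.allclose(sums, self.n, atol=1e-9):
            raise ValueError("column sums of counts must all equal n")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n

    def is_palindromic(self, tol: float = 1e-12) -> bool:
        f = self.frequencies
        return bool(np.max(np.abs(f - f[::-1, ::-1])) <= tol)


@dataclass(frozen=True)
class IndividualInformationModel:
    """Ri scoring engine: weights, entropies, correction and conservation."""

    pfm: PositionFrequencyMatrix
    e_n: float
    entropies: np.ndarray          # H(l), bits
    weights: np.ndarray            # Riw(b, l), bits; -inf where policy says so
    rsequence: float
    zero_count_policy: str         # "minus_infinity" or "pseudocount"
    pseudocount: float = 0.0

    @property
    def width(self) -> int:
        return self.pfm.width

    def score(self, s: NucleotideSequence | str) -> float:
        return ri_score(self, s)

    def consensus(self) -> NucleotideSequence:
        return consensus(self)


def encode(residues: str) -> np.ndarray:
    """Map an ACGT string to integer codes 0..3; raises on other symbols."""
    try:
        return np.array([_BASE_INDEX[c] for c in residues.upper()], dtype=np.int64)
    except KeyError as exc:
        raise AlphabetError(f"non-ACGT symbol {exc.args[0]!r} in sequence") from None


def build_pfm(seqs: list[NucleotideSequence | str], width: int | None = None) -> PositionFrequencyMatrix:
    """Tally per-column base counts of an alignment of equal-length sequences."""
    residues = [s.residues if isinstance(s, NucleotideSequence) else s for s in seqs]
    if len(residues) < 2:
        raise ValueError("need at least 2 sequences to build a frequency matrix")
    L = width if width is not None else len(residues[0])
    counts = np.zeros((4, L))
    for i, r in enumerate(residues):
        if len(r) != L:
            raise ValueError(
                f"alignment error: sequence {i} has length {len(r)}, expected {L}"
            )
        codes = encode(r)
        np.add.at(counts, (codes, np.arange(L)), 1.0)
    return PositionFrequencyMatrix(counts=counts, n=len(residues))


def _entropy_of_counts(parts: tuple[int, ...], n: int) -> float:
    return -sum((c / n) * math.log2(c / n) for c in parts if c > 0)


def small_sample_correction(
    n: int,
    method: str = "exact_enumeration",
    n_samples: int = 1000,
    seed: int = 0,
) -> float:
    """Expected entropy bias e(n) = 2 - E[H_obs] for n uniform base draws.

    ``exact_enumeration`` sums over all base-count compositions of n with
    multinomial weights (iterating ordered partitions of n into <= 4 parts, so
    it is fast for n up to a few hundred).  ``monte_carlo`` averages the
    plug-in entropy of ``n_samples`` simulated alignments; use it for large n.
    """
    if n < 1:
        raise ValueError("e(n) requires n >= 1")
    if method == "exact_enumeration":
        log_nfact = math.lgamma(n + 1)
        ln4n = n * math.log(4.0)
        expected_h = 0.0
        # partitions a >= b >= c >= d with a+b+c+d == n
        for a in range((n + 3) // 4, n + 1):
            for b in range(min(a, n - a), -1, -1):
                rem = n - a - b
                if rem > 2 * b:
                    break
                for c in range(min(b, rem), -1, -1):
                    d = rem - c
                    if d > c:
                        break
                    parts = (a, b, c, d)
                    mult = len(set(permutations(parts)))
                    logp = (
                        log_nfact
                        - sum(math.lgamma(p + 1) for p in parts)
                        - ln4n
                    )
                    expected_h += mult * math.exp(logp) * _entropy_of_counts(parts, n)
        return 2.0 - expected_h
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, [0.25] * 4, size=n_samples)
        f = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(f > 0, f * np.log2(f), 0.0), axis=1)
        return 2.0 - float(h.mean())
    raise ValueError(f"unknown e(n) method {method!r}")


def build_model(
    pfm: PositionFrequencyMatrix,
    zero_count_policy: str = "minus_infinity",
    pseudocount: float = 0.25,
    e_method: str = "exact_enumeration",
) -> IndividualInformationModel:
    """Derive weights, entropies and Rsequence from a frequency matrix.

    Under the default ``minus_infinity`` policy a base never seen at a position
    scores -inf, and the mean Ri of the training alignment equals Rsequence to
    machine precision.  The ``pseudocount`` policy adds ``pseudocount`` to
    every count before forming scoring frequencies (entropies and Rsequence
    still use the raw frequencies), so held-out sequences always score finite.
    """
    if zero_count_policy not in {"minus_infinity", "pseudocount"}:
        raise ValueError(f"unknown zero-count policy {zero_count_policy!r}")
    e_n = small_sample_correction(pfm.n, method=e_method)
    f = pfm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(f > 0, f * np.log2(f), 0.0), axis=0)
    rsequence = float(np.sum(2.0 - h - e_n))
    if zero_count_policy == "pseudocount":
        f_score = (pfm.counts + pseudocount) / (pfm.n + 4 * pseudocount)
        weights = 2.0 + np.log2(f_score) - e_n
    else:
        with np.errstate(divide="ignore"):
            weights = np.where(f > 0, 2.0 + np.log2(np.where(f > 0, f, 1.0)) - e_n, -np.inf)
    return IndividualInformationModel(
        pfm=pfm,
        e_n=e_n,
        entropies=h,
        weights=weights,
        rsequence=rsequence,
        zero_count_policy=zero_count_policy,
        pseudocount=pseudocount if zero_count_policy == "pseudocount" else 0.0,
    )


def build_model_from_sequences(
    seqs: list[NucleotideSequence | str],
    palindromic: bool = False,
    zero_count_policy: str = "minus_infinity",
    pseudocount: float = 0.25,
) -> IndividualInformationModel:
    """Build a model straight from aligned sequences.

    With ``palindromic=True`` the alignment is pooled with its reverse
    complements before counting (2n rows), which constrains the frequency
    matrix to be strand-symmetric; the small-sample correction then uses the
    pooled row count, since under the null the mirrored column adds
    independent draws.
    """
    residues = [s.residues if isinstance(s, NucleotideSequence) else s for s in seqs]
    if palindromic:
        residues = residues + [reverse_complement(r) for r in residues]
    return build_model(
        build_pfm(residues), zero_count_policy=zero_count_policy, pseudocount=pseudocount
    )


def ri_score(model: IndividualInformationModel, s: NucleotideSequence | str) -> float:
    """Individual information Ri(s) = sum_l Riw(s_l, l), in bits."""
    residues = s.residues if isinstance(s, NucleotideSequence) else s
    if len(residues) != model.width:
        raise ScoringError(
            f"sequence length {len(residues)} does not match model width {model.width}"
        )
    codes = encode(residues)
    return float(model.weights[codes, np.arange(model.width)].sum())


def consensus(model: IndividualInformationModel, with_ties: bool = False):
    """Per-position argmax-frequency sequence; ties broken in A<C<G<T order.

    With ``with_ties=True`` also returns the list of 0-based tied positions.
    """
    f = model.pfm.frequencies
    best = np.argmax(f, axis=0)  # first (A<C<G<T) index on ties
    seq = NucleotideSequence("consensus", "".join(ALPHABET[i] for i in best))
    if not with_ties:
        return seq
    ties = [
        l for l in range(model.width)
        if np.sum(np.isclose(f[:, l], f[best[l], l], atol=1e-12)) > 1
    ]
    return seq, ties


def logo_data(model: IndividualInformationModel) -> list[list[tuple[str, float]]]:
    """Sequence-logo stacks: per position, (base, letter height in bits).

    The stack height at position l is ``max(0, 2 - H(l) - e(n))`` and letters
    partition it proportionally to their frequencies, smallest first (the
    usual drawing order).  Clamping is presentational only; Rsequence itself
    is never clamped.
    """
    f = model.pfm.frequencies
    stacks = []
    for l in range(model.width):
        height = max(0.0, 2.0 - model.entropies[l] - model.e_n)
        letters = sorted(
            ((ALPHABET[b], float(f[b, l] * height)) for b in range(4)),
            key=lambda t: (t[1], t[0]),
        )
        stacks.append([(b, h) for b, h in letters if h > 0])
    return stacks


# -- plain-text serialization (bit-exact round trip via hex floats) ----------

_MODEL_MAGIC = "# argbox individual-information model v1"


def save_model(model: IndividualInformationModel, path) -> None:
    """Serialize a model; floats are stored as C99 hex to round-trip exactly."""
    with open(path, "w") as fh:
        fh.write(_MODEL_MAGIC + "\n")
        fh.write(f"width\t{model.width}\n")
        fh.write(f"n\t{model.pfm.n}\n")
        fh.write(f"e_n\t{model.e_n.hex()}\t{model.e_n:.6f}\n")
        fh.write(f"rsequence\t{model.rsequence.hex()}\t{model.rsequence:.6f}\n")
        fh.write(f"policy\t{model.zero_count_policy}\t{model.pseudocount.hex()}\n")
        fh.write("# Riw(b,l): one row per position, columns A C G T (hex bits)\n")
        for l in range(model.width):
            fh.write(
                "\t".join(_hex(model.weights[b, l]) for b in range(4)) + "\n"
            )
        fh.write("# counts n(b,l): one row per position, columns A C G T\n")
        for l in range(model.width):
            fh.write(
                "\t".join(repr(int(model.pfm.counts[b, l])) for b in range(4)) + "\n"
            )


def _hex(x: float) -> str:
    return "-inf" if x == -np.inf else float(x).hex()


def _unhex(tok: str) -> float:
    return -np.inf if tok == "-inf" else float.fromhex(tok)


def load_model(path) -> IndividualInformationModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _MODEL_MAGIC:
        raise ValueError(f"{path}: not an argbox model file")
    header = {}
    body_start = None
    for i, ln in enumerate(lines[1:], start=1):
        if ln.startswith("#"):
            body_start = i + 1
            break
        key, *vals = ln.split("\t")
        header[key] = vals
    width = int(header["width"][0])
    n = int(header["n"][0])
    policy, pc_hex = header["policy"][0], header["policy"][1]
    weight_rows = lines[body_start : body_start + width]
    count_rows = lines[body_start + width + 1 : body_start + 2 * width + 1]
    weights = np.array([[_unhex(t) for t in row.split("\t")] for row in weight_rows]).T
    counts = np.array([[int(t) for t in row.split("\t")] for row in count_rows], dtype=float).T
    pfm = PositionFrequencyMatrix(counts=counts, n=n)
    f = pfm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(f > 0, f * np.log2(f), 0.0), axis=0)
    return IndividualInformationModel(
        pfm=pfm,
        e_n=_unhex(header["e_n"][0]),
        entropies=h,
        weights=weights,
        rsequence=_unhex(header["rsequence"][0]),
        zero_count_policy=policy,
        pseudocount=_unhex(pc_hex),
    )
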