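"""Genome scanning with the ARG box model.

A length-L window slides over both strands of the input sequence.  Each
window gets two numbers:

* its individual information Ri in bits (always against the 2-bit uniform
  reference, so scores are comparable with the published per-box values), and
* an exact upper-tail p-value computed by dynamic programming over the
  discrete distribution of the log-odds score ``sum_l log2 f(x_l, l)/q(x_l)``
  of a random L-mer under a 0-order background q.

By default q is the scanned sequence's own base composition, so p-values are
composition-aware (a match this strong in a 72%-GC genome is rarer than the
same match in a balanced one) while Ri stays on the uniform reference scale.
Windows are kept when they pass BOTH published filters: p-value below
``p_max`` (default 1e-5) and Ri above ``ri_min`` (default 10.0 bits).

Kept single-box hits are then assembled into binding sites — single boxes,
contiguous tandems (gap 0) and 1-nt-gap tandems — and associated with
annotated genes downstream of the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boxdata import BindingSiteArchitecture
from .iimodel import IndividualInformationModel, encode
from .seqio import ALPHABET, GenomicInterval, NucleotideSequence

__all__ = [
    "ScoreDistribution",
    "ScanHit",
    "AssembledSite",
    "GeneAnnotation",
    "ResolutionError",
    "score_distribution",
    "log_odds_weights",
    "pvalue",
    "scan",
    "assemble_sites",
    "associate_genes",
    "distance_to_start",
]

logger = logging.getLogger("argbox.scanner")

DEFAULT_P_MAX = 1e-5
DEFAULT_RI_MIN = 10.0
DEFAULT_GRANULARITY = 1e-3


class ResolutionError(ValueError):
    """Score binning too coarse for the weight matrix support."""


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact pmf of a weight-matrix score of a random L-mer under a 0-order
    background, binned at ``granularity`` bits.

    ``pmf[k]`` is the probability of binned score ``(k + offset) *
    granularity``; ``sf`` is the inclusive upper-tail cumulative.
    """

    granularity: float
    offset: int
    pmf: np.ndarray
    sf: np.ndarray
    background: np.ndarray

    @property
    def support_min(self) -> float:
        return self.offset * self.granularity

    @property
    def support_max(self) -> float:
        return (self.offset + len(self.pmf) - 1) * self.granularity

    def pvalue(self, score: float) -> float:
        return pvalue(self, score)


def _finite_weights(weights: np.ndarray, floor: float | None) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.isneginf(w).any():
        if floor is None:
            finite_min = w[np.isfinite(w)].min()
            floor = finite_min - 10.0
        w = np.where(np.isneginf(w), floor, w)
    return w


def score_distribution(
    weights: np.ndarray,
    background: np.ndarray,
    granularity: float = DEFAULT_GRANULARITY,
    neg_inf_floor: float | None = None,
) -> ScoreDistribution:
    """Position-wise convolution of per-position score pmfs under q.

    ``weights`` is a (4, L) matrix in bits; -inf cells are replaced by
    ``neg_inf_floor`` (default: 10 bits below the smallest finite weight)
    before binning.  Deterministic; exact up to the binning.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0, atol=1e-9) or (q <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    w = _finite_weights(weights, neg_inf_floor)
    w_int = np.round(w / granularity).astype(np.int64)
    support = int(w_int.max(axis=0).sum() - w_int.min(axis=0).sum()) + 1
    if support < 10:
        raise ResolutionError(
            f"granularity {granularity} collapses the score support to {support} bins"
        )
    pmf = np.array([1.0])
    offset = 0
    for l in range(w.shape[1]):
        col = w_int[:, l]
        new_offset = offset + int(col.min())
        new = np.zeros(len(pmf) + int(col.max() - col.min()))
        for b in range(4):
            shift = offset + int(col[b]) - new_offset
            new[shift : shift + len(pmf)] += pmf * q[b]
        pmf, offset = new, new_offset
    sf = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(
        granularity=granularity, offset=offset, pmf=pmf, sf=sf, background=q
    )


def pvalue(dist: ScoreDistribution, score: float) -> float:
    """Pr(binned score >= score), rounding the query down a bin (conservative)."""
    k = int(np.floor(score / dist.granularity)) - dist.offset
    if k < 0:
        return 1.0
    if k >= len(dist.sf):
        return float(dist.sf[-1])
    return float(dist.sf[k])


def log_odds_weights(
    model: IndividualInformationModel,
    background: np.ndarray,
    neg_inf_floor: float | None = None,
) -> np.ndarray:
    """FIMO-style log2(f/q) weight matrix for the p-value statistic."""
    f = model.pfm.frequencies
    q = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        lod = np.where(f > 0, np.log2(np.where(f > 0, f, 1.0) / q[:, None]), -np.inf)
    return _finite_weights(lod, neg_inf_floor)


@dataclass(frozen=True)
class ScanHit:
    """A scored window: location, strand, Ri (bits) and upper-tail p-value."""

    interval: GenomicInterval
    strand: str
    ri: float
    p_value: float


@dataclass(frozen=True)
class AssembledSite:
    """A binding site assembled from 1-2 box hits."""

    architecture: BindingSiteArchitecture
    hits: tuple[ScanHit, ...]
    combined_score: float

    @property
    def interval(self) -> GenomicInterval:
        chrom = self.hits[0].interval.chrom
        return GenomicInterval(
            chrom,
            min(h.interval.left for h in self.hits),
            max(h.interval.right for h in self.hits),
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its start codon position (1-based first base of ATG/GTG)."""

    gene_id: str
    chrom: str
    strand: str
    start_codon: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.left <= self.start_codon <= self.right):
            raise ValueError(f"{self.gene_id}: start codon outside gene span")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: gene strand must be '+' or '-'")


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Sliding sums of per-position weights; windows with non-ACGT score NaN."""
    L = weights.shape[1]
    n_win = len(codes) - L + 1
    lut = np.vstack([weights, np.full((1, L), np.nan)])  # code 4 = ambiguous
    scores = np.zeros(n_win)
    for l in range(L):
        scores += lut[codes[l : l + n_win], l]
    return scores


def _encode_loose(residues: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def scan(
    genome: NucleotideSequence,
    model: IndividualInformationModel,
    p_max: float = DEFAULT_P_MAX,
    ri_min: float = DEFAULT_RI_MIN,
    background: np.ndarray | None = None,
    granularity: float = DEFAULT_GRANULARITY,
    circular: bool = False,
) -> list[ScanHit]:
    """Scan both strands, keeping windows with p-value < p_max AND Ri > ri_min.

    ``background`` defaults to the scanned sequence's own 0-order composition.
    Windows containing a non-ACGT symbol are skipped (a summary is logged).
    With ``circular=True`` the first L-1 wraparound windows are also scored.
    """
    L = model.width
    codes = _encode_loose(genome.residues)
    if circular:
        codes = np.concatenate([codes, codes[: L - 1]])
    if len(codes) < L:
        return []
    if background is None:
        counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
        background = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    lod = log_odds_weights(model, background)
    dist = score_distribution(lod, background, granularity)
    riw = _finite_weights(model.weights, None)
    # minus-strand score at window i equals the mirrored-complement matrix
    # applied to the forward encoding
    lod_rc = lod[::-1, ::-1]
    riw_rc = riw[::-1, ::-1]

    ri_f = _window_scores(codes, riw)
    ri_r = _window_scores(codes, riw_rc)
    lod_f = _window_scores(codes, lod)
    lod_r = _window_scores(codes, lod_rc)

    n_skipped = int(np.isnan(ri_f).sum())
    if n_skipped:
        logger.info("skipped %d windows containing non-ACGT symbols", n_skipped)

    # p < p_max as a score threshold: smallest binned score whose sf <= p_max
    hits: list[ScanHit] = []
    glen = len(genome.residues)
    for strand, ri_s, lod_s in (("+", ri_f, lod_f), ("-", ri_r, lod_r)):
        with np.errstate(invalid="ignore"):
            keep = np.flatnonzero((ri_s > ri_min) & ~np.isnan(lod_s))
        for i in keep:
            p = pvalue(dist, float(lod_s[i]))
            if p < p_max:
                left = int(i) + 1  # wraparound windows keep right > genome length
                hits.append(
                    ScanHit(
                        interval=GenomicInterval(genome.id, left, left + L - 1, strand),
                        strand=strand,
                        ri=float(ri_s[i]),
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.left, h.strand))
    return hits


def assemble_sites(hits: list[ScanHit], max_gap: int = 1) -> list[AssembledSite]:
    """Greedy left-to-right assembly of box hits into binding sites.

    Duplicate windows (the same interval reported on both strands, as happens
    with a strand-symmetric model) are collapsed to one box first, and hits
    overlapping an already-accepted box are dropped; then consecutive boxes
    with an inter-box gap of 0 or 1 nt are paired into tandem sites, leftover
    boxes becoming singles.  No hit is used twice; with three mutually
    adjacent boxes the leftmost pair wins.
    """
    ordered = sorted(hits, key=lambda h: (h.interval.chrom, h.interval.left, -h.ri, h.strand))
    boxes: list[ScanHit] = []
    for h in ordered:
        if boxes and boxes[-1].interval.chrom == h.interval.chrom:
            prev = boxes[-1]
            if h.interval.left <= prev.interval.right:  # duplicate or overlap
                continue
        boxes.append(h)
    sites: list[AssembledSite] = []
    i = 0
    while i < len(boxes):
        if i + 1 < len(boxes) and boxes[i].interval.chrom == boxes[i + 1].interval.chrom:
            gap = boxes[i + 1].interval.left - boxes[i].interval.right - 1
            if 0 <= gap <= max_gap:
                kind = "tandem_contiguous" if gap == 0 else "tandem_gap1"
                pair = (boxes[i], boxes[i + 1])
                sites.append(
                    AssembledSite(
                        architecture=BindingSiteArchitecture(
                            kind=kind,
                            member_box_ids=tuple(
                                f"{h.interval.chrom}:{h.interval.left}-{h.interval.right}"
                                for h in pair
                            ),
                            gap_nt=gap,
                        ),
                        hits=pair,
                        combined_score=pair[0].ri + pair[1].ri,
                    )
                )
                i += 2
                continue
        h = boxes[i]
        sites.append(
            AssembledSite(
                architecture=BindingSiteArchitecture(
                    kind="single",
                    member_box_ids=(
                        f"{h.interval.chrom}:{h.interval.left}-{h.interval.right}",
                    ),
                ),
                hits=(h,),
                combined_score=h.ri,
            )
        )
        i += 1
    return sites


def distance_to_start(site: GenomicInterval, gene: GeneAnnotation) -> int:
    """Signed nt count from the site edge proximal to the gene (in its
    reading direction) to the base before the start codon; negative when the
    site overlaps or passes the start."""
    if site.chrom != gene.chrom:
        raise ValueError(
            f"site on {site.chrom} and gene {gene.gene_id} on {gene.chrom}"
        )
    if gene.strand == "+":
        return gene.start_codon - site.right - 1
    return site.left - gene.start_codon - 1


def associate_genes(
    sites: list[AssembledSite | GenomicInterval],
    annotation: list[GeneAnnotation],
    max_next: int = 1,
) -> list[list[tuple[str, int, str]]]:
    """Map each site to the nearest gene whose start codon lies downstream of
    the site (respecting gene strand) plus up to ``max_next`` following genes;
    a gene whose span contains the site is also reported.

    Returns, per site, a list of ``(gene_id, distance_to_start, relation)``
    with relation one of ``downstream`` / ``next`` / ``contains``.  Empty
    annotation yields empty mappings (with a warning).
    """
    if not annotation:
        logger.warning("gene association requested with empty annotation")
        return [[] for _ in sites]
    out: list[list[tuple[str, int, str]]] = []
    for site in sites:
        iv = site.interval if isinstance(site, AssembledSite) else site
        genes = [g for g in annotation if g.chrom == iv.chrom]
        candidates = []
        for g in genes:
            downstream = (
                g.start_codon >= iv.left if g.strand == "+" else g.start_codon <= iv.right
            )
            if downstream:
                candidates.append((distance_to_start(iv, g), g))
        candidates.sort(key=lambda t: (t[0], t[1].gene_id))
        entries: list[tuple[str, int, str]] = []
        for rank, (d, g) in enumerate(candidates[: 1 + max_next]):
            entries.append((g.gene_id, d, "downstream" if rank == 0 else "next"))
        for g in genes:
            if g.left <= iv.left and iv.right <= g.right and g.gene_id not in {e[0] for e in entries}:
                entries.append((g.gene_id, distance_to_start(iv, g), "contains"))
        if not entries:
            logger.warning(
                "site %s:%d-%d has no downstream gene in the annotation",
                iv.chrom, iv.left, iv.right,
            )
        out.append(entries)
    return out
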