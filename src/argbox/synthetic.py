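"""Synthetic data generation for end-to-end testing of the pipeline.

Everything needed to exercise the model builder, scanner and motif
discovery without any external downloads:

* i.i.d. high-GC background genomes (default 72% GC, the Streptomyces
  genomic context),
* planted operator boxes sampled from a model's frequency matrix, either
  free-strength or rejection-sampled to a target Ri, arranged as single
  boxes or tandem pairs with 0- or 1-nt gaps,
* labeled positive/negative probe sets emulating band-shift (EMSA) probe
  collections,
* ground-truth bookkeeping for sensitivity/precision evaluation.

All generators take an explicit seed and use numpy's PCG64 generator, so
truth sets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxdata import BindingSiteArchitecture
from .iimodel import IndividualInformationModel, ri_score
from .seqio import ALPHABET, GenomicInterval, NucleotideSequence

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedSite",
    "SyntheticTruthSet",
    "PlacementError",
    "generate_background",
    "sample_box",
    "sample_box_with_ri",
    "plant_sites",
    "generate_probe_sets",
    "evaluate_hits",
]

RNG_ALGORITHM = "numpy.PCG64"
DEFAULT_GC = 0.72
MAX_REJECTION_ATTEMPTS = 100_000


class PlacementError(RuntimeError):
    """Could not place the requested sites under the spacing constraints."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Conditions for a planted-site genome."""

    length: int
    n_sites: int
    gc: float = DEFAULT_GC
    seed: int = 0
    architecture_mix: dict = field(
        default_factory=lambda: {"single": 1.0}
    )
    strength: str = "sample_from_pfm"        # or "fixed_ri_target"
    ri_target: float | None = None
    ri_tolerance: float = 0.5
    min_spacing: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        total = sum(self.architecture_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("architecture_mix proportions must sum to 1")
        unknown = set(self.architecture_mix) - {"single", "tandem_contiguous", "tandem_gap1"}
        if unknown:
            raise ValueError(f"unknown architectures {unknown}")
        if self.strength == "fixed_ri_target" and self.ri_target is None:
            raise ValueError("fixed_ri_target requires ri_target")


@dataclass(frozen=True)
class PlantedSite:
    interval: GenomicInterval            # full site span, 1-based inclusive
    strand: str
    architecture: BindingSiteArchitecture
    box_intervals: tuple[GenomicInterval, ...]
    sequences: tuple[str, ...]           # box sequences as planted (site strand)
    ri: tuple[float, ...]


@dataclass(frozen=True)
class SyntheticTruthSet:
    spec: SyntheticGenomeSpec
    sites: tuple[PlantedSite, ...]
    rng_algorithm: str = RNG_ALGORITHM


def generate_background(length: int, gc: float = DEFAULT_GC, seed: int = 0) -> NucleotideSequence:
    """i.i.d. background with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    residues = "".join(ALPHABET[c] for c in codes)
    return NucleotideSequence(f"synthetic_gc{gc:g}_seed{seed}", residues)


def sample_box(model: IndividualInformationModel, rng: np.random.Generator) -> str:
    """One box drawn per-position from the model's frequency matrix."""
    f = model.pfm.frequencies
    return "".join(ALPHABET[rng.choice(4, p=f[:, l])] for l in range(model.width))


def sample_box_with_ri(
    model: IndividualInformationModel,
    rng: np.random.Generator,
    target: float,
    tolerance: float = 0.5,
    max_attempts: int = MAX_REJECTION_ATTEMPTS,
) -> str:
    """Rejection-sample a box until its Ri falls within target +/- tolerance."""
    for _ in range(max_attempts):
        s = sample_box(model, rng)
        if abs(ri_score(model, s) - target) <= tolerance:
            return s
    raise PlacementError(
        f"no box with Ri in [{target - tolerance}, {target + tolerance}] "
        f"after {max_attempts} attempts"
    )


def _site_span(arch: str, width: int) -> int:
    if arch == "single":
        return width
    return 2 * width + (0 if arch == "tandem_contiguous" else 1)


def _choose_positions(rng, length, spans, min_spacing, max_tries=10_000):
    """Positions (0-based starts) drawn without replacement, min_spacing apart."""
    placed: list[tuple[int, int]] = []  # (start, end) half-open, padded
    starts = []
    for span in spans:
        for _ in range(max_tries):
            pos = int(rng.integers(0, length - span + 1))
            lo, hi = pos - min_spacing, pos + span + min_spacing
            if all(hi <= s or lo >= e for s, e in placed):
                placed.append((pos, pos + span))
                starts.append(pos)
                break
        else:
            raise PlacementError(
                f"could not place {len(spans)} sites of spans {set(spans)} "
                f"in length {length} with spacing {min_spacing}"
            )
    return starts


def plant_sites(
    background: NucleotideSequence,
    model: IndividualInformationModel,
    spec: SyntheticGenomeSpec,
) -> tuple[NucleotideSequence, SyntheticTruthSet]:
    """Embed boxes into a background genome and return the ground truth.

    Site positions are drawn without replacement honoring ``min_spacing``;
    strands are random; tandem architectures plant two boxes with the
    requested gap.  Box sequences come from :func:`sample_box` or, under
    ``fixed_ri_target``, from :func:`sample_box_with_ri`.
    """
    rng = np.random.default_rng(spec.seed)
    L = model.width
    archs = sorted(spec.architecture_mix)
    probs = np.array([spec.architecture_mix[a] for a in archs])
    chosen = [archs[i] for i in rng.choice(len(archs), size=spec.n_sites, p=probs)]
    spans = [_site_span(a, L) for a in chosen]
    if sum(sp + spec.min_spacing for sp in spans) > len(background.residues):
        raise PlacementError("spec infeasible for background length")
    starts = _choose_positions(rng, len(background.residues), spans, spec.min_spacing)

    residues = list(background.residues)
    sites = []
    for arch, span, start in zip(chosen, spans, starts):
        n_boxes = 1 if arch == "single" else 2
        gap = {"single": 0, "tandem_contiguous": 0, "tandem_gap1": 1}[arch]
        if spec.strength == "fixed_ri_target":
            boxes = [
                sample_box_with_ri(model, rng, spec.ri_target, spec.ri_tolerance)
                for _ in range(n_boxes)
            ]
        else:
            boxes = [sample_box(model, rng) for _ in range(n_boxes)]
        strand = "+" if rng.integers(2) == 0 else "-"
        # '.' marks the spacer base, left as background
        site_seq = boxes[0] if n_boxes == 1 else boxes[0] + "." * gap + boxes[1]
        if strand == "-":
            cmap = {"A": "T", "C": "G", "G": "C", "T": "A", ".": "."}
            planted = "".join(cmap[c] for c in reversed(site_seq))
        else:
            planted = site_seq
        for k, ch in enumerate(planted):
            if ch != ".":
                residues[start + k] = ch
        box_ivs = []
        offs = [0] if n_boxes == 1 else [0, L + gap]
        for off in offs:
            box_ivs.append(
                GenomicInterval(background.id, start + off + 1, start + off + L)
            )
        arch_obj = BindingSiteArchitecture(
            kind=arch,
            member_box_ids=tuple(f"{iv.left}-{iv.right}" for iv in box_ivs),
            gap_nt=None if arch == "single" else gap,
        )
        sites.append(
            PlantedSite(
                interval=GenomicInterval(background.id, start + 1, start + span),
                strand=strand,
                architecture=arch_obj,
                box_intervals=tuple(box_ivs),
                sequences=tuple(boxes),
                ri=tuple(ri_score(model, b) for b in boxes),
            )
        )
    genome = NucleotideSequence(background.id + "_planted", "".join(residues))
    sites.sort(key=lambda s: s.interval.left)
    return genome, SyntheticTruthSet(spec=spec, sites=tuple(sites))


def generate_probe_sets(
    model: IndividualInformationModel,
    n_pos: int = 30,
    n_neg: int = 20,
    probe_len: int = 200,
    seed: int = 0,
    gc: float = DEFAULT_GC,
    tandem_prob: float = 0.5,
    return_truth: bool = False,
) -> tuple:
    """Labeled probe sets standing in for an EMSA probe collection.

    Positives carry one planted box (or a contiguous tandem pair, with
    probability ``tandem_prob``) at a random position and strand; negatives
    are pure background of matched length and composition.  With
    ``return_truth=True`` a third element records, per positive probe,
    ``(probe_id, offset, strand, planted box sequences)``.
    """
    if probe_len < model.width:
        raise ValueError("probe_len must be >= model width")
    rng = np.random.default_rng(seed)
    from .seqio import reverse_complement

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    L = model.width

    def bg(n, label):
        codes = rng.choice(4, size=n, p=p)
        return "".join(ALPHABET[c] for c in codes)

    positives = []
    truth = []
    for i in range(n_pos):
        residues = list(bg(probe_len, i))
        tandem = rng.random() < tandem_prob
        span = 2 * L if tandem else L
        start = int(rng.integers(0, probe_len - span + 1))
        boxes = [sample_box(model, rng) for _ in range(2 if tandem else 1)]
        insert = "".join(boxes)
        strand = "+"
        if rng.integers(2) == 1:
            insert = reverse_complement(insert)
            strand = "-"
        residues[start : start + span] = insert
        positives.append(NucleotideSequence(f"pos_{i}", "".join(residues)))
        truth.append((f"pos_{i}", start, strand, tuple(boxes)))
    negatives = [
        NucleotideSequence(f"neg_{i}", bg(probe_len, i)) for i in range(n_neg)
    ]
    if return_truth:
        return positives, negatives, truth
    return positives, negatives


def write_truth_tsv(truth: SyntheticTruthSet, path) -> None:
    """Serialize a truth set as TSV (one row per planted site)."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tleft\tright\tstrand\tkind\tgap\tbox_lefts\tbox_rights\t"
            "sequences\tri\n"
        )
        for s in truth.sites:
            gap = s.architecture.gap_nt
            fh.write(
                "\t".join(
                    [
                        s.interval.chrom,
                        str(s.interval.left),
                        str(s.interval.right),
                        s.strand,
                        s.architecture.kind,
                        "." if gap is None else str(gap),
                        ",".join(str(iv.left) for iv in s.box_intervals),
                        ",".join(str(iv.right) for iv in s.box_intervals),
                        ",".join(s.sequences),
                        ",".join(f"{r:.6f}" for r in s.ri),
                    ]
                )
                + "\n"
            )


def read_truth_tsv(path) -> SyntheticTruthSet:
    """Read a truth set written by :func:`write_truth_tsv`.

    The generating spec is not recoverable from the table; a placeholder
    spec is attached.
    """
    sites = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a truth-set TSV")
        for line in fh:
            (chrom, left, right, strand, kind, gap, blefts, brights, seqs, ris) = (
                line.rstrip("\n").split("\t")
            )
            box_ivs = tuple(
                GenomicInterval(chrom, int(l), int(r))
                for l, r in zip(blefts.split(","), brights.split(","))
            )
            sites.append(
                PlantedSite(
                    interval=GenomicInterval(chrom, int(left), int(right)),
                    strand=strand,
                    architecture=BindingSiteArchitecture(
                        kind=kind,
                        member_box_ids=tuple(f"{iv.left}-{iv.right}" for iv in box_ivs),
                        gap_nt=None if gap == "." else int(gap),
                    ),
                    box_intervals=box_ivs,
                    sequences=tuple(seqs.split(",")),
                    ri=tuple(float(x) for x in ris.split(",")),
                )
            )
    placeholder = SyntheticGenomeSpec(length=1, n_sites=len(sites) or 1)
    return SyntheticTruthSet(spec=placeholder, sites=tuple(sites))


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    return max(0, min(a.right, b.right) - max(a.left, b.left) + 1)


def evaluate_hits(
    hits,
    truth: SyntheticTruthSet,
    min_overlap_frac: float = 0.5,
) -> dict:
    """Sensitivity and precision of a scan against a planted truth set.

    A planted site counts as recovered when any (deduplicated) hit window
    overlaps one of its boxes by at least ``min_overlap_frac`` of the box
    length; a hit counts as true when it overlaps any planted box that way.
    Hits reported on both strands at the same window (strand-symmetric
    models) are collapsed first.
    """
    unique: dict[tuple, object] = {}
    for h in hits:
        unique.setdefault((h.interval.left, h.interval.right), h)
    boxes = [(site, iv) for site in truth.sites for iv in site.box_intervals]
    recovered = set()
    n_true_hits = 0
    for (left, right), h in unique.items():
        hit_true = False
        for k, (site, iv) in enumerate(boxes):
            need = int(np.ceil(min_overlap_frac * len(iv)))
            if _overlap(h.interval, iv) >= need:
                hit_true = True
                recovered.add(id(site))
        n_true_hits += int(hit_true)
    n_sites = len(truth.sites)
    per_arch: dict[str, list[int]] = {}
    for site in truth.sites:
        k = site.architecture.kind
        per_arch.setdefault(k, [0, 0])
        per_arch[k][1] += 1
        if id(site) in recovered:
            per_arch[k][0] += 1
    return {
        "n_sites": n_sites,
        "n_hits": len(unique),
        "n_true_hits": n_true_hits,
        "sensitivity": len(recovered) / n_sites if n_sites else float("nan"),
        "precision": n_true_hits / len(unique) if unique else float("nan"),
        "per_architecture": {
            k: {"recovered": v[0], "planted": v[1]} for k, v in per_arch.items()
        },
    }
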