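"""The curated ARG box collection and binding-site architecture rules.

Ships the 44 experimentally supported ARG boxes of the S. coelicolor ArgR
regulon study as a TSV fixture: 20-nt box sequences, chromosomal coordinates,
distance(s) to the regulated start codon, the published per-box Ri and the
curation footnote flags.  Seven boxes are flagged ``c`` ("not included in the
model"); the remaining 37 well-conserved boxes form the training set of the
ARG box model.

ArgR binding sites come in three architectures: a single box, two contiguous
tandem boxes (gap 0), or two tandem boxes separated by one nucleotide
(gap 1).  One locus (rstP) carries two boxes separated by 10 nt whose status
— one composite site or two independent ones — is undecided; the classifier
reports such pairs as ``paired_other`` and leaves the decision to the user.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .seqio import GenomicInterval, NucleotideSequence

__all__ = [
    "ArgBoxRecord",
    "BindingSiteArchitecture",
    "CurationError",
    "DataIntegrityError",
    "GeometryError",
    "load_table1",
    "load_box_table",
    "select_training_set",
    "classify_architecture",
    "TABLE1_SHA256",
]

CHROMOSOME = "SCO_chromosome"

# checksum of the packaged fixture; guards against silent corruption
TABLE1_SHA256 = "a8a528208b243a3cd60fe44a654c8517a1e88ad3b26d43c37e0a677b5dc1d00a"

# beyond this separation two lone boxes at one locus are independent sites
PAIRING_DISTANCE_NT = 25


class CurationError(ValueError):
    """Training-set selection received an unexpected record collection."""


class DataIntegrityError(RuntimeError):
    """Packaged fixture does not match its recorded checksum."""


class GeometryError(ValueError):
    """Box coordinates are inconsistent (e.g. overlapping boxes)."""


@dataclass(frozen=True)
class ArgBoxRecord:
    """One curated ARG box: sequence, location and published annotation."""

    gene_code: str
    gene_name: str
    box_id: str
    sequence: NucleotideSequence
    interval: GenomicInterval
    distance_to_start: tuple[int, ...]
    printed_ri: float
    flags: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"{self.box_id}: sequence length {len(self.sequence)} != "
                f"interval span {len(self.interval)}"
            )
        if not self.flags <= set("abcdef"):
            raise ValueError(f"{self.box_id}: unknown flags {self.flags - set('abcdef')}")

    @property
    def in_training_set(self) -> bool:
        return "c" not in self.flags

    @property
    def site_key(self) -> tuple[str, str]:
        """Grouping key (locus prefix, site letter) parsed from the box id.

        Box ids end in ``_<letter?><digit>``: the optional letter labels the
        site within the locus, the digit numbers the box within the site
        (0 = lone box).  E.g. ``AB.SCO1580_B1`` -> ("AB.SCO1580", "B").
        """
        prefix, _, suffix = self.box_id.rpartition("_")
        m = re.fullmatch(r"([A-Za-z]*)(\d+)", suffix)
        letter = m.group(1) if m else ""
        return (prefix, letter)


@dataclass(frozen=True)
class BindingSiteArchitecture:
    """Architecture of one assembled binding site."""

    kind: str  # single | tandem_contiguous | tandem_gap1 | paired_other
    member_box_ids: tuple[str, ...]
    gap_nt: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"single", "tandem_contiguous", "tandem_gap1", "paired_other"}:
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.kind == "single" and len(self.member_box_ids) != 1:
            raise ValueError("single sites have exactly one member box")
        if self.kind == "tandem_contiguous" and self.gap_nt != 0:
            raise ValueError("contiguous tandem requires gap 0")
        if self.kind == "tandem_gap1" and self.gap_nt != 1:
            raise ValueError("tandem_gap1 requires gap 1")


def _parse_distance(text: str) -> tuple[int, ...]:
    return tuple(int(tok) for tok in str(text).split("|"))


def load_box_table(path_or_buffer) -> list[ArgBoxRecord]:
    """Parse a box table in the fixture TSV dialect (see data/table1.tsv)."""
    df = pd.read_csv(path_or_buffer, sep="\t", keep_default_na=False, dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ArgBoxRecord(
                gene_code=row.gene_code,
                gene_name=row.gene_name,
                box_id=row.box_id,
                sequence=NucleotideSequence(row.box_id, row.sequence),
                interval=GenomicInterval(CHROMOSOME, int(row.left), int(row.right)),
                distance_to_start=_parse_distance(row.distance),
                printed_ri=float(row.ri),
                flags=frozenset(row.flags),
            )
        )
    return records


def load_table1(verify_checksum: bool = True) -> list[ArgBoxRecord]:
    """Load the 44 packaged ARG box records, in table order."""
    data = resources.files("argbox.data").joinpath("table1.tsv").read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        if digest != TABLE1_SHA256:
            raise DataIntegrityError(
                f"packaged box table checksum mismatch: {digest} != {TABLE1_SHA256}"
            )
    import io

    records = load_box_table(io.BytesIO(data))
    if len(records) != 44:
        raise DataIntegrityError(f"expected 44 box records, found {len(records)}")
    return records


def select_training_set(records: list[ArgBoxRecord]) -> list[ArgBoxRecord]:
    """Apply the published curation: drop boxes flagged ``c``, keep order.

    On the packaged table this keeps exactly the 37 well-conserved boxes used
    to build the final model.
    """
    if not records:
        raise CurationError("no records supplied")
    kept = [r for r in records if r.in_training_set]
    if len({r.box_id for r in records}) != len(records):
        raise CurationError("duplicate box ids in input")
    return kept


def classify_architecture(records: list[ArgBoxRecord]) -> list[BindingSiteArchitecture]:
    """Classify binding-site architectures from box coordinates.

    Boxes are grouped by locus (``site_key`` locus prefix).  Within a locus,
    coordinate-sorted boxes are paired greedily left to right when separated
    by 0 or 1 nt (``gap = left2 - right1 - 1``); remaining lone boxes become
    ``single`` unless exactly two leftover neighbours lie within
    ``PAIRING_DISTANCE_NT``, which are reported as ``paired_other`` with the
    gap recorded.  Overlapping boxes (gap < 0) raise :class:`GeometryError`.
    """
    by_locus: dict[str, list[ArgBoxRecord]] = {}
    for r in records:
        by_locus.setdefault(r.site_key[0], []).append(r)

    sites: list[BindingSiteArchitecture] = []
    for locus in by_locus:
        boxes = sorted(by_locus[locus], key=lambda r: r.interval.left)
        for a, b in zip(boxes, boxes[1:]):
            gap = b.interval.left - a.interval.right - 1
            if gap < 0:
                raise GeometryError(
                    f"boxes {a.box_id} and {b.box_id} overlap (gap {gap})"
                )
        used = [False] * len(boxes)
        # first pass: true tandems (gap 0 or 1)
        i = 0
        while i < len(boxes) - 1:
            gap = boxes[i + 1].interval.left - boxes[i].interval.right - 1
            if not used[i] and not used[i + 1] and gap in (0, 1):
                sites.append(
                    BindingSiteArchitecture(
                        kind="tandem_contiguous" if gap == 0 else "tandem_gap1",
                        member_box_ids=(boxes[i].box_id, boxes[i + 1].box_id),
                        gap_nt=gap,
                    )
                )
                used[i] = used[i + 1] = True
                i += 2
            else:
                i += 1
        # second pass: nearby leftover pairs (undecided composite sites)
        leftovers = [j for j in range(len(boxes)) if not used[j]]
        for j, k in zip(leftovers, leftovers[1:]):
            if used[j] or used[k] or k != j + 1:
                continue
            gap = boxes[k].interval.left - boxes[j].interval.right - 1
            if gap <= PAIRING_DISTANCE_NT:
                sites.append(
                    BindingSiteArchitecture(
                        kind="paired_other",
                        member_box_ids=(boxes[j].box_id, boxes[k].box_id),
                        gap_nt=gap,
                    )
                )
                used[j] = used[k] = True
        for j in range(len(boxes)):
            if not used[j]:
                sites.append(
                    BindingSiteArchitecture(
                        kind="single", member_box_ids=(boxes[j].box_id,)
                    )
                )
    sites.sort(key=lambda s: s.member_box_ids)
    return sites


def training_sequences(records: list[ArgBoxRecord] | None = None) -> list[NucleotideSequence]:
    """Convenience: the 37 training box sequences (fixture order)."""
    if records is None:
        records = load_table1()
    return [r.sequence for r in select_training_set(records)]
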