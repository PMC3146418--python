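"""Degenerate-consensus motif scanning and promoter mapping.

Implements prediction of catabolite-responsive elements (cre) — the DNA
operators bound by the CcpA regulator in low-GC Gram-positive bacteria —
by scanning a genome on both strands against a degenerate IUPAC consensus
(canonically the 14-mer ``TGWNANCGNTNWCA``) with a mismatch budget that
applies only to conserved positions and never to the exempt center
positions (the invariant ``CG`` core).  Hits are then mapped into gene
promoter regions using a translation-start-relative coordinate with the
no-zero convention (−1 is the base immediately 5' of the A of ATG, +1 is
that A itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to their allowed base sets.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Default cre consensus used throughout the package.
CRE_CONSENSUS = "TGWNANCGNTNWCA"
#: 1-based positions of the invariant CG core, where no mismatch is tolerated.
CRE_EXEMPT_POSITIONS = (7, 8)
#: Mismatch budget over conserved, non-exempt positions.
CRE_MAX_MISMATCHES = 2

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class ConsensusParseError(ValueError):
    """Raised when a consensus string contains a non-IUPAC character."""


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate consensus with a conserved-position mismatch budget.

    Parameters
    ----------
    positions
        Allowed-base set per position, 5'→3'.
    conserved_mask
        True where the allowed set is a strict subset of {A,C,G,T}.
    center_exempt_mask
        True at positions where no mismatch is tolerated at all; every
        exempt position must also be conserved.
    max_mismatches
        Mismatch budget applied over conserved, non-exempt positions.
    """

    positions: tuple[frozenset[str], ...]
    conserved_mask: tuple[bool, ...]
    center_exempt_mask: tuple[bool, ...]
    max_mismatches: int

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("pattern must have length >= 1")
        if self.max_mismatches < 0:
            raise ValueError("mismatch budget must be nonnegative")
        for i, (exempt, conserved) in enumerate(
            zip(self.center_exempt_mask, self.conserved_mask), start=1
        ):
            if exempt and not conserved:
                raise ValueError(
                    f"exempt position {i} is not conserved (allowed set is N)"
                )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def conserved_positions(self) -> tuple[int, ...]:
        """1-based indices of conserved positions."""
        return tuple(i for i, c in enumerate(self.conserved_mask, 1) if c)

    def allowed_matrix(self) -> np.ndarray:
        """Boolean (length × 4) matrix of allowed bases in A,C,G,T order."""
        mat = np.zeros((len(self), 4), dtype=bool)
        for i, allowed in enumerate(self.positions):
            for b in allowed:
                mat[i, _BASE_INDEX[b]] = True
        return mat


@dataclass(frozen=True)
class MotifHit:
    """One genomic consensus match.

    Coordinates are 0-based half-open on the forward strand of ``contig``;
    ``matched_seq`` is the sequence as read on the hit strand.
    """

    contig: str
    start: int
    end: int
    strand: str
    matched_seq: str
    mismatch_count: int


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS annotation; cds_start/cds_end are 1-based inclusive."""

    locus: str
    name: str
    contig: str
    strand: str
    cds_start: int
    cds_end: int
    category: str = "unknown"

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.locus}: cds_start > cds_end")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus}: strand must be + or -")

    @property
    def translation_start(self) -> int:
        """1-based genomic position of the first base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end


@dataclass(frozen=True)
class PromoterHit:
    """A motif hit placed relative to a gene's translation start.

    ``rel_position`` uses the no-zero convention: −1 is the base
    immediately 5' of the start codon on the coding strand, +1 is the
    first base of the start codon.
    """

    locus: str
    hit: MotifHit
    rel_position: int

    def __post_init__(self) -> None:
        if self.rel_position == 0:
            raise ValueError("rel_position 0 is not a valid coordinate")


def parse_consensus(
    text: str,
    exempt_positions: Iterable[int] = (),
    budget: int = 0,
) -> ConsensusPattern:
    """Parse an IUPAC consensus string into a :class:`ConsensusPattern`.

    Parameters
    ----------
    text
        IUPAC nucleotide string, e.g. ``"TGWNANCGNTNWCA"``.
    exempt_positions
        1-based positions at which no mismatch is tolerated (must be
        conserved positions).
    budget
        Mismatch budget over the remaining conserved positions.
    """
    positions = []
    for i, ch in enumerate(text.upper(), start=1):
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise ConsensusParseError(
                f"non-IUPAC character {ch!r} at position {i}"
            )
        positions.append(allowed)
    conserved = tuple(len(a) < 4 for a in positions)
    exempt_set = set(int(i) for i in exempt_positions)
    for i in exempt_set:
        if not 1 <= i <= len(positions):
            raise ValueError(f"exempt position {i} out of range 1..{len(positions)}")
        if not conserved[i - 1]:
            raise ValueError(f"exempt position {i} is not conserved")
    exempt = tuple(i + 1 in exempt_set for i in range(len(positions)))
    return ConsensusPattern(tuple(positions), conserved, exempt, int(budget))


def cre_pattern() -> ConsensusPattern:
    """The default cre consensus: TGWNANCGNTNWCA, CG core exempt, budget 2."""
    return parse_consensus(CRE_CONSENSUS, CRE_EXEMPT_POSITIONS, CRE_MAX_MISMATCHES)


def mismatch_profile(seq: str, pattern: ConsensusPattern) -> tuple[int, bool]:
    """Count conserved-position mismatches and test the exempt center.

    Returns ``(count, center_ok)`` where ``count`` is the number of
    conserved, non-exempt positions whose base falls outside the allowed
    set and ``center_ok`` is True iff every exempt position matches.
    Non-conserved (N) positions never contribute.
    """
    seq = seq.upper()
    if len(seq) != len(pattern):
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}"
        )
    count = 0
    center_ok = True
    for base, allowed, conserved, exempt in zip(
        seq, pattern.positions, pattern.conserved_mask, pattern.center_exempt_mask
    ):
        if base not in _BASE_INDEX:
            raise ValueError(f"ambiguous or invalid base {base!r} in sequence")
        if not conserved:
            continue
        if base in allowed:
            continue
        if exempt:
            center_ok = False
        else:
            count += 1
    return count, center_ok


def matches(seq: str, pattern: ConsensusPattern) -> bool:
    """True iff the exempt center is intact and mismatches fit the budget."""
    count, center_ok = mismatch_profile(seq, pattern)
    return center_ok and count <= pattern.max_mismatches


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return str(Seq(seq).reverse_complement())


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A,C,G,T→0..3, anything else→4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[ord(b)] = i
    return codes[arr]


def _scan_one_strand(
    codes: np.ndarray, pattern: ConsensusPattern
) -> tuple[np.ndarray, np.ndarray]:
    """Return (window starts, mismatch counts) of matching windows.

    Windows containing any non-ACGT base are skipped.
    """
    m = len(pattern)
    n = codes.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    allowed = pattern.allowed_matrix()  # (m, 4)
    # per pattern position j, a 5-entry lookup: True = mismatch/invalid
    bad = np.ones((m, 5), dtype=bool)
    bad[:, :4] = ~allowed
    mism = np.zeros(n, dtype=np.int16)
    center_bad = np.zeros(n, dtype=bool)
    ambig = np.zeros(n, dtype=bool)
    for j in range(m):
        col = codes[j : j + n]
        ambig |= col == 4
        is_bad = bad[j][col]
        if pattern.center_exempt_mask[j]:
            center_bad |= is_bad
        elif pattern.conserved_mask[j]:
            mism += is_bad
    ok = (~ambig) & (~center_bad) & (mism <= pattern.max_mismatches)
    starts = np.nonzero(ok)[0]
    return starts, mism[starts].astype(int)


def scan(
    genome: Mapping[str, str], pattern: ConsensusPattern, dedupe_overlap: bool = False
) -> list[MotifHit]:
    """Scan both strands of every contig for consensus matches.

    Parameters
    ----------
    genome
        Mapping of contig name → sequence (A/C/G/T plus ambiguity codes;
        windows containing ambiguous bases are skipped).
    pattern
        The consensus to match.
    dedupe_overlap
        When True, collapse reverse-complement hit pairs that occupy the
        identical genomic footprint, keeping the forward-strand hit.

    Returns
    -------
    Hits sorted by (contig, start, strand); forward and reverse matches at
    the same footprint are both reported unless ``dedupe_overlap``.
    """
    m = len(pattern)
    hits: list[MotifHit] = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        codes = _encode(seq)
        fwd_starts, fwd_mm = _scan_one_strand(codes, pattern)
        for s, mm in zip(fwd_starts, fwd_mm):
            hits.append(MotifHit(contig, int(s), int(s) + m, "+", seq[s : s + m], int(mm)))
        rc = reverse_complement(seq)
        rc_starts, rc_mm = _scan_one_strand(_encode(rc), pattern)
        L = len(seq)
        for s, mm in zip(rc_starts, rc_mm):
            start = L - int(s) - m  # mirror back to forward coordinates
            hits.append(MotifHit(contig, start, start + m, "-", rc[s : s + m], int(mm)))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    if dedupe_overlap:
        deduped: list[MotifHit] = []
        seen_fwd = {(h.contig, h.start) for h in hits if h.strand == "+"}
        for h in hits:
            if h.strand == "-" and (h.contig, h.start) in seen_fwd:
                # keep only the + strand partner at an identical footprint
                fwd = next(
                    x
                    for x in hits
                    if x.contig == h.contig and x.start == h.start and x.strand == "+"
                )
                if reverse_complement(h.matched_seq) == fwd.matched_seq:
                    continue
            deduped.append(h)
        hits = deduped
    return hits


def map_to_promoters(
    hits: Sequence[MotifHit],
    annotations: Sequence[GeneAnnotation],
    window: tuple[int, int] = (-300, 15),
    contig_lengths: Mapping[str, int] | None = None,
) -> list[PromoterHit]:
    """Place motif hits relative to gene translation starts.

    A hit is assigned to every gene for which the 5'-most base of its
    footprint on that gene's coding strand falls inside ``window``
    (``(min_rel, max_rel)``, no-zero convention).  A hit may therefore map
    to several genes (divergent promoters); hit strand is not required to
    match gene strand.
    """
    min_rel, max_rel = window
    if min_rel >= max_rel:
        raise ValueError("window min must be < window max")
    hit_contigs = {h.contig for h in hits}
    known = hit_contigs if contig_lengths is None else set(contig_lengths)
    missing = [a.locus for a in annotations if hits and a.contig not in known]
    if missing and contig_lengths is not None:
        raise ValueError(f"annotations reference unknown contigs: {missing}")
    out: list[PromoterHit] = []
    by_contig: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    for ann in annotations:
        ts = ann.translation_start
        for h in by_contig.get(ann.contig, []):
            if ann.strand == "+":
                pos = h.start + 1  # 1-based leftmost base = 5'-most on + strand
                rel = pos - ts if pos < ts else pos - ts + 1
            else:
                pos = h.end  # 1-based rightmost base = 5'-most on - strand
                rel = ts - pos if pos > ts else ts - pos + 1
            if min_rel <= rel <= max_rel:
                out.append(PromoterHit(ann.locus, h, rel))
    out.sort(key=lambda p: (p.locus, p.hit.start, p.hit.strand))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into a {contig: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_ANNOT_COLUMNS = ["locus", "name", "contig", "strand", "cds_start", "cds_end", "category"]


def read_annotations_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read the simple tab-separated annotation format.

    Columns: locus, name, contig, strand, cds_start, cds_end, category.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_ANNOT_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    anns = []
    for row in df.itertuples(index=False):
        anns.append(
            GeneAnnotation(
                locus=row.locus,
                name=getattr(row, "name", row.locus) or row.locus,
                contig=row.contig,
                strand=row.strand,
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                category=getattr(row, "category", "unknown") or "unknown",
            )
        )
    return anns


def write_annotations_tsv(annotations: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            (a.locus, a.name, a.contig, a.strand, a.cds_start, a.cds_end, a.category)
            for a in annotations
        ],
        columns=_ANNOT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_annotations_gff(path: str | Path) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    anns = []
    for feat in db.features_of_type("CDS"):
        locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", [feat.id]))[0]
        name = feat.attributes.get("gene", feat.attributes.get("Name", [locus]))[0]
        category = feat.attributes.get("category", ["unknown"])[0]
        anns.append(
            GeneAnnotation(
                locus=locus,
                name=name,
                contig=feat.seqid,
                strand=feat.strand,
                cds_start=feat.start,
                cds_end=feat.end,
                category=category,
            )
        )
    return anns


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Dispatch on extension: .gff/.gff3 → GFF3, otherwise TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return read_annotations_gff(path)
    return read_annotations_tsv(path)


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Write hits as BED6 (0-based half-open; score = mismatch count)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.matched_seq}\t"
                f"{h.mismatch_count}\t{h.strand}\n"
            )


def read_hits_bed(path: str | Path) -> list[MotifHit]:
    """Read BED6 written by :func:`write_hits_bed`."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            contig, start, end, seq, score, strand = line.split("\t")
            hits.append(MotifHit(contig, int(start), int(end), strand, seq, int(score)))
    return hits


def write_promoter_table(promoter_hits: Sequence[PromoterHit], path: str | Path) -> None:
    """Write promoter hits as TSV: locus, sequence, position, plus hit coordinates."""
    pd.DataFrame(
        [
            (
                p.locus,
                p.hit.matched_seq,
                p.rel_position,
                p.hit.contig,
                p.hit.start,
                p.hit.end,
                p.hit.strand,
                p.hit.mismatch_count,
            )
            for p in promoter_hits
        ],
        columns=[
            "locus",
            "sequence",
            "position",
            "contig",
            "start",
            "end",
            "strand",
            "mismatches",
        ],
    ).to_csv(path, sep="\t", index=False)


def known_cre_sites() -> pd.DataFrame:
    """Curated putative cre sites upstream of ribose-induced L. sakei 23K genes.

    Columns: locus, gene, sequence (14-mer on the reported strand) and
    position (translation-start-relative, no-zero convention).
    """
    path = Path(__file__).parent / "data" / "known_cre_sites.tsv"
    return pd.read_csv(path, sep="\t")
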