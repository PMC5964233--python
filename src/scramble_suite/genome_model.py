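"""Annotated synthetic-chromosome model, segmentation and sequence rendering.

A synthetic chromosome is a linear sequence partitioned by symmetric Cre
recombination sites (loxPsym) into *segments*.  A segment is *essential* when
it carries at least one essential gene or an essential chromosomal element
(centromere, telomere); deleting it is lethal, which is the constraint that
shapes which rearrangements survive selection.

Coordinates are 0-based, half-open throughout (BED convention); GFF3 input is
converted on read.  Each recombination motif belongs to the junction between
two segments, not to either segment, so segment spans plus motif spans tile
the chromosome exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _dna
from ._dna import LOXPSYM, as_array, revcomp, to_str


class AnnotationError(ValueError):
    """Raised when annotations are inconsistent with the reference."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoxSite:
    """One Cre recombination motif on the reference.

    ``kind`` is ``"loxPsym"`` for the symmetric SCRaMbLE sites and ``"loxP"``
    for the asymmetric reporter-cassette sites, which never recombine with the
    symmetric ones.
    """

    id: int
    position: int          # 0-based motif start
    length: int = 34
    kind: str = "loxPsym"  # {"loxPsym", "loxP"}
    orientation: str = "symmetric"  # {"fwd", "rev", "symmetric"}

    def __post_init__(self):
        if self.kind == "loxPsym" and self.orientation != "symmetric":
            raise AnnotationError("loxPsym sites must be symmetric")

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass(frozen=True)
class GeneFeature:
    name: str
    start: int
    end: int
    strand: str = "+"
    essential: bool = False


@dataclass(frozen=True)
class Segment:
    """Inter-site interval; ``essential`` if it holds an essential gene or
    an essential chromosomal element."""

    index: int
    start: int
    end: int
    essential: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair.

    ``tag_class`` is one of ``junction`` (flanks a loxPsym site),
    ``pcrtag_syn`` / ``pcrtag_wt`` (chromosome-version-specific PCRtag
    primers).  ``order`` is the along-chromosome rank used by segregation
    mapping; ``megachunk`` the coordinate landmark label.
    """

    name: str
    fwd: str
    rev: str
    max_product: int = 5000
    tag_class: str = "junction"
    order: int = -1
    megachunk: str = ""

    def __post_init__(self):
        if len(self.fwd) < 15 or len(self.rev) < 15:
            raise AnnotationError(f"primers of {self.name} must be >= 15 bp")


@dataclass
class ChromosomeMap:
    """Fully annotated linear reference chromosome."""

    name: str
    length: int
    sequence: np.ndarray | None = None      # uint8 ASCII, length == length
    sites: list[LoxSite] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    centromere: tuple[int, int] | None = None
    telomeres: tuple[tuple[int, int], tuple[int, int]] | None = None
    pcrtags: list[PrimerPair] = field(default_factory=list)
    megachunks: list[tuple[str, int, int]] = field(default_factory=list)
    synthetic: bool = True

    # -- derived -----------------------------------------------------------
    @property
    def loxpsym_sites(self) -> list[LoxSite]:
        return [s for s in self.sites if s.kind == "loxPsym"]

    @property
    def loxp_sites(self) -> list[LoxSite]:
        return [s for s in self.sites if s.kind == "loxP"]

    @property
    def site_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.loxpsym_sites], dtype=np.int64)

    @property
    def motif_length(self) -> int:
        sites = self.loxpsym_sites
        return sites[0].length if sites else len(LOXPSYM)

    def segment_sequence(self, index: int, orientation: int = 1) -> np.ndarray:
        if self.sequence is None:
            raise ValueError("map carries no sequence")
        seg = self.segments[index]
        sub = self.sequence[seg.start:seg.end]
        return sub if orientation > 0 else revcomp(sub)

    def motif_sequence(self, site_index: int) -> np.ndarray:
        site = self.loxpsym_sites[site_index]
        return self.sequence[site.position:site.end]

    def centromere_segment(self) -> int | None:
        if self.centromere is None:
            return None
        c0, c1 = self.centromere
        for seg in self.segments:
            if seg.start < c1 and c0 < seg.end:
                return seg.index
        return None

    def validate(self, require_centromere: bool = False) -> None:
        for s in self.sites:
            if s.position < 0 or s.end > self.length:
                raise AnnotationError(f"site {s.id} out of bounds")
        psym = sorted(self.loxpsym_sites, key=lambda s: s.position)
        for a, b in zip(psym, psym[1:]):
            if b.position < a.end:
                raise AnnotationError(
                    f"overlapping loxPsym motifs at {a.position} and {b.position}"
                )
        for g in self.genes:
            if g.start < 0 or g.end > self.length or g.start >= g.end:
                raise AnnotationError(f"gene {g.name} span out of bounds")
        if require_centromere and self.centromere is None:
            raise AnnotationError("centromere annotation required")


@dataclass
class SegmentPath:
    """An ordered list of oriented segment copies: one (possibly rearranged)
    chromosome.  Orientation is +1 (reference) or -1 (reverse complement)."""

    steps: list[tuple[int, int]]
    provenance: list = field(default_factory=list)

    @classmethod
    def reference(cls, cmap: ChromosomeMap) -> "SegmentPath":
        return cls(steps=[(i, 1) for i in range(len(cmap.segments))])

    def __len__(self) -> int:
        return len(self.steps)

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentPath) and self.steps == list(other.steps)

    def segment_counts(self, n_segments: int) -> np.ndarray:
        counts = np.zeros(n_segments, dtype=np.int64)
        for seg, _ in self.steps:
            counts[seg] += 1
        return counts

    def is_reference(self, n_segments: int) -> bool:
        return self.steps == [(i, 1) for i in range(n_segments)]


# ---------------------------------------------------------------------------
# segmentation & summaries
# ---------------------------------------------------------------------------

def build_segments(
    length: int,
    sites: list[LoxSite],
    genes: list[GeneFeature],
    centromere: tuple[int, int] | None,
    telomeres: tuple[tuple[int, int], tuple[int, int]] | None,
) -> list[Segment]:
    """Partition [0, length) at loxPsym motifs and derive essentiality."""
    psym = sorted((s for s in sites if s.kind == "loxPsym"), key=lambda s: s.position)
    bounds = [0]
    for s in psym:
        bounds.extend([s.position, s.end])
    bounds.append(length)
    spans = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]

    essential_intervals = [(g.start, g.end) for g in genes if g.essential]
    if centromere is not None:
        essential_intervals.append(tuple(centromere))
    if telomeres is not None:
        essential_intervals.extend(tuple(t) for t in telomeres)

    segments = []
    for idx, (a, b) in enumerate(spans):
        ess = any(a < e1 and e0 < b for e0, e1 in essential_intervals)
        segments.append(Segment(index=idx, start=a, end=b, essential=ess))
    return segments


def essential_summary(cmap: ChromosomeMap) -> tuple[int, int]:
    """(number of essential segments, number of essential genes)."""
    if not cmap.segments:
        raise ValueError("segmentation not computed")
    n_seg = sum(1 for s in cmap.segments if s.essential)
    n_gene = sum(1 for g in cmap.genes if g.essential)
    return n_seg, n_gene


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def scan_lox_sites(sequence, motif=LOXPSYM, kind: str | None = None) -> list[LoxSite]:
    """All occurrences of ``motif`` on either strand, one site per locus.

    Palindromic motifs match identically on both strands and are reported
    once.  For asymmetric motifs the strand is recorded as orientation.
    """
    motif_arr = as_array(motif)
    if len(motif_arr) == 0:
        raise ValueError("motif must be non-empty")
    seq_b = as_array(sequence).tobytes()
    fwd = _dna.find_all(seq_b, motif_arr.tobytes())
    palindrome = _dna.is_palindrome(motif_arr)
    hits: dict[int, str] = {p: "fwd" for p in fwd}
    if palindrome:
        orientation = {p: "symmetric" for p in fwd}
    else:
        orientation = dict(hits)
        for p in _dna.find_all(seq_b, revcomp(motif_arr).tobytes()):
            orientation.setdefault(p, "rev")
    if kind is None:
        kind = "loxPsym" if palindrome else "loxP"
    return [
        LoxSite(id=i, position=p, length=len(motif_arr), kind=kind,
                orientation=orientation[p])
        for i, p in enumerate(sorted(orientation))
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_sequence(path: SegmentPath, cmap: ChromosomeMap) -> np.ndarray:
    """Concatenate oriented segment sequences with exactly one recombination
    motif at each junction.

    The motif placed at a junction is the reference motif adjacent to the
    exiting segment end (its reverse complement for inverted segments); for
    the palindromic loxPsym motif all choices are byte-identical, which is
    what makes breakpoints inside the motif intrinsically ambiguous.
    """
    if cmap.sequence is None:
        raise ValueError("map carries no sequence")
    n = len(cmap.segments)
    parts: list[np.ndarray] = []
    for i, (seg, orient) in enumerate(path.steps):
        if not 0 <= seg < n:
            raise IndexError(f"segment index {seg} out of range")
        parts.append(cmap.segment_sequence(seg, orient))
        if i < len(path.steps) - 1:
            parts.append(_junction_motif(cmap, path.steps[i], path.steps[i + 1]))
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)


def _junction_motif(cmap, exit_step, enter_step) -> np.ndarray:
    n_sites = len(cmap.loxpsym_sites)

    def motif_for(step, leaving):
        seg, orient = step
        if orient > 0:
            idx = seg if leaving else seg - 1
        else:
            idx = seg - 1 if leaving else seg
        if 0 <= idx < n_sites:
            m = cmap.motif_sequence(idx)
            return m if orient > 0 else revcomp(m)
        return None

    m = motif_for(exit_step, leaving=True)
    if m is None:
        m = motif_for(enter_step, leaving=False)
    if m is None:  # both ends terminal segments: fall back to canonical motif
        m = as_array(LOXPSYM)
    return m


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(path, name: str, sequence: np.ndarray, wrap: int = 80) -> None:
    rec = SeqRecord(Seq(to_str(sequence)), id=name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    return {rec.id: as_array(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_sites_bed(path, cmap: ChromosomeMap) -> None:
    """BED6: one row per recombination site; name encodes the kind."""
    with open(path, "w") as fh:
        for s in sorted(cmap.sites, key=lambda s: s.position):
            strand = "-" if s.orientation == "rev" else "+"
            fh.write(f"{cmap.name}\t{s.position}\t{s.end}\t{s.kind}_{s.id}\t0\t{strand}\n")


def read_sites_bed(path, chrom: str | None = None) -> list[LoxSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if chrom is not None and f[0] != chrom:
                raise AnnotationError(f"BED chromosome {f[0]!r} != {chrom!r}")
            start, end = int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else "loxPsym"
            kind = "loxP" if name.startswith("loxP_") or name == "loxP" else "loxPsym"
            strand = f[5] if len(f) > 5 else "+"
            orientation = "symmetric" if kind == "loxPsym" else ("rev" if strand == "-" else "fwd")
            sites.append(LoxSite(id=len(sites), position=start, length=end - start,
                                 kind=kind, orientation=orientation))
    return sorted(sites, key=lambda s: s.position)


_GFF_SITE_TYPES = {"recombination_feature", "loxPsym_site", "loxP_site"}


def write_gff3(path, cmap: ChromosomeMap) -> None:
    """GFF3 with genes (``essential=true|false``), sites, centromere, telomeres."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {cmap.name} 1 {cmap.length}\n")
        for g in cmap.genes:
            attrs = f"ID={g.name};Name={g.name};essential={'true' if g.essential else 'false'}"
            fh.write(f"{cmap.name}\tscramble_suite\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
        for s in cmap.sites:
            ftype = "loxPsym_site" if s.kind == "loxPsym" else "loxP_site"
            strand = "-" if s.orientation == "rev" else "+"
            fh.write(f"{cmap.name}\tscramble_suite\t{ftype}\t{s.position + 1}\t{s.end}\t.\t{strand}\t.\tID=site_{s.id}\n")
        if cmap.centromere:
            c0, c1 = cmap.centromere
            fh.write(f"{cmap.name}\tscramble_suite\tcentromere\t{c0 + 1}\t{c1}\t.\t.\t.\tID=CEN\n")
        if cmap.telomeres:
            for i, (t0, t1) in enumerate(cmap.telomeres):
                fh.write(f"{cmap.name}\tscramble_suite\ttelomere\t{t0 + 1}\t{t1}\t.\t.\t.\tID=TEL{i}\n")


def read_gff3(path):
    """Parse genes/sites/centromere/telomeres from GFF3 (1-based, inclusive)."""
    from gffutils.iterators import DataIterator

    genes, sites, centromere, telomeres = [], [], None, []
    chrom = None
    for feat in DataIterator(str(path)):
        chrom = chrom or feat.seqid
        start, end = feat.start - 1, feat.end
        if feat.featuretype == "gene":
            ess = (feat.attributes.get("essential", ["false"])[0].lower() == "true")
            name = feat.attributes.get("Name", feat.attributes.get("ID", ["gene"]))[0]
            genes.append(GeneFeature(name=name, start=start, end=end,
                                     strand=feat.strand or "+", essential=ess))
        elif feat.featuretype in _GFF_SITE_TYPES:
            kind = "loxP" if feat.featuretype == "loxP_site" else "loxPsym"
            orientation = ("symmetric" if kind == "loxPsym"
                           else ("rev" if feat.strand == "-" else "fwd"))
            sites.append(LoxSite(id=len(sites), position=start, length=end - start,
                                 kind=kind, orientation=orientation))
        elif feat.featuretype == "centromere":
            centromere = (start, end)
        elif feat.featuretype == "telomere":
            telomeres.append((start, end))
    telo = tuple(sorted(telomeres)) if len(telomeres) == 2 else None
    return chrom, genes, sorted(sites, key=lambda s: s.position), centromere, telo


def load_chromosome(fasta_path, annotation_path, require_centromere: bool = False) -> ChromosomeMap:
    """Build a fully populated map from a FASTA reference plus annotations.

    ``annotation_path`` may be a BED6 site list (genes empty), a GFF3 file
    carrying genes/sites/centromere/telomeres, or a JSON map produced by
    :func:`save_map`.
    """
    records = read_fasta(fasta_path)
    annotation_path = Path(annotation_path)
    if annotation_path.suffix == ".json":
        cmap = load_map(annotation_path)
        if cmap.name not in records:
            raise AnnotationError(f"FASTA lacks record {cmap.name!r}")
        cmap.sequence = records[cmap.name]
        if len(cmap.sequence) != cmap.length:
            raise AnnotationError("FASTA length does not match map length")
        cmap.validate(require_centromere)
        return cmap

    if annotation_path.suffix in {".gff", ".gff3"}:
        chrom, genes, sites, centromere, telomeres = read_gff3(annotation_path)
        if chrom not in records:
            raise AnnotationError(f"FASTA lacks record {chrom!r}")
    else:
        if len(records) != 1:
            raise AnnotationError("BED annotation requires a single-record FASTA")
        chrom = next(iter(records))
        sites = read_sites_bed(annotation_path, chrom)
        genes, centromere, telomeres = [], None, None

    seq = records[chrom]
    cmap = ChromosomeMap(name=chrom, length=len(seq), sequence=seq, sites=sites,
                         genes=genes, centromere=centromere, telomeres=telomeres)
    cmap.validate(require_centromere)
    cmap.segments = build_segments(cmap.length, sites, genes, centromere, telomeres)
    return cmap


def map_to_dict(cmap: ChromosomeMap) -> dict:
    d = {
        "name": cmap.name,
        "length": cmap.length,
        "synthetic": cmap.synthetic,
        "sites": [asdict(s) for s in cmap.sites],
        "genes": [asdict(g) for g in cmap.genes],
        "segments": [asdict(s) for s in cmap.segments],
        "centromere": list(cmap.centromere) if cmap.centromere else None,
        "telomeres": [list(t) for t in cmap.telomeres] if cmap.telomeres else None,
        "pcrtags": [asdict(p) for p in cmap.pcrtags],
        "megachunks": [list(m) for m in cmap.megachunks],
    }
    return d


def map_from_dict(d: dict) -> ChromosomeMap:
    cmap = ChromosomeMap(
        name=d["name"], length=d["length"], synthetic=d.get("synthetic", True),
        sites=[LoxSite(**s) for s in d["sites"]],
        genes=[GeneFeature(**g) for g in d["genes"]],
        segments=[Segment(**s) for s in d["segments"]],
        centromere=tuple(d["centromere"]) if d.get("centromere") else None,
        telomeres=tuple(tuple(t) for t in d["telomeres"]) if d.get("telomeres") else None,
        pcrtags=[PrimerPair(**p) for p in d.get("pcrtags", [])],
        megachunks=[tuple(m) for m in d.get("megachunks", [])],
    )
    return cmap


def save_map(path, cmap: ChromosomeMap) -> None:
    with open(path, "w") as fh:
        json.dump(map_to_dict(cmap), fh, indent=1)


def load_map(path) -> ChromosomeMap:
    with open(path) as fh:
        return map_from_dict(json.load(fh))


def path_to_dict(path: SegmentPath) -> dict:
    return {"steps": [[s, o] for s, o in path.steps],
            "provenance": [getattr(e, "as_tuple", lambda: e)() if hasattr(e, "as_tuple") else list(e)
                           for e in path.provenance]}


def path_from_dict(d: dict) -> SegmentPath:
    return SegmentPath(steps=[(int(s), int(o)) for s, o in d["steps"]])
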