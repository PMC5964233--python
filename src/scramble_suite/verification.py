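"""In-silico PCR verification and backcross segregation mapping.

Junction PCR asks whether a rearrangement changed the amplicon a primer
pair produces across a recombination site; PCRtag profiling distinguishes
synthetic from native chromosome versions by version-specific primer pairs;
segregation mapping intersects tag presence across phenotype-split spore
pools to localise a causal region.  Primer matching is exact on both
strands — presence and size are used qualitatively, with no thermodynamic
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import as_array, find_all, revcomp_bytes
from .genome_model import ChromosomeMap, PrimerPair


@dataclass
class AmpliconPrediction:
    name: str
    products: list[tuple[int, int, int, str]]  # (start, end, length, orientation)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted(p[2] for p in self.products))

    @property
    def present(self) -> bool:
        return bool(self.products)


def predict_amplicons(genome, pair: PrimerPair,
                      max_product: int | None = None) -> AmpliconPrediction:
    """All inward-facing exact placements of a primer pair within the size cap.

    Both template orientations are scanned: the pair also amplifies from a
    region whose sequence was inverted, in which case the product is reported
    with orientation '-'.
    """
    for p in (pair.fwd, pair.rev):
        if any(b not in "ACGTacgt" for b in p):
            raise ValueError(f"primer of {pair.name} contains ambiguous bases")
    cap = max_product if max_product is not None else pair.max_product
    g = as_array(genome).tobytes()
    fwd = pair.fwd.upper().encode()
    rev = pair.rev.upper().encode()
    products = []
    for orientation, left, right in (("+", fwd, revcomp_bytes(rev)),
                                     ("-", rev, revcomp_bytes(fwd))):
        lhits = find_all(g, left)
        rhits = find_all(g, right)
        for i in lhits:
            for j in rhits:
                end = j + len(right)
                if j >= i and end - i <= cap:
                    products.append((i, end, end - i, orientation))
    return AmpliconPrediction(name=pair.name, products=sorted(products))


def pcrtag_profile(genome, tags: list[PrimerPair]) -> pd.DataFrame:
    """Presence/absence of each PCRtag's synthetic and wild-type versions.

    Returns a boolean DataFrame indexed by tag name with columns
    ``syn`` / ``wt`` (absent versions default to False).
    """
    names = sorted({t.name for t in tags})
    df = pd.DataFrame(False, index=names, columns=["syn", "wt"])
    for t in tags:
        col = {"pcrtag_syn": "syn", "pcrtag_wt": "wt"}.get(t.tag_class)
        if col is None:
            continue
        df.loc[t.name, col] = predict_amplicons(genome, t).present
    return df


@dataclass
class SegregationResult:
    """Candidate causal regions from phenotype-split pools."""

    regions: list[tuple[str, str, list[str]]]  # (first tag, last tag, megachunks)
    concordance: pd.Series                     # per-tag concordant with phenotype


def segregation_map(
    tolerant_profiles: list[pd.DataFrame] | pd.DataFrame,
    intolerant_profiles: list[pd.DataFrame] | pd.DataFrame,
    tag_order: list[str],
    megachunk_of: dict[str, str] | None = None,
) -> SegregationResult:
    """Localise the region whose synthetic tags co-segregate with phenotype.

    A tag is concordant when its synthetic version is present in every
    tolerant sample and absent from every intolerant sample (perfect
    concordance; no tag-error model).  Maximal runs of concordant tags along
    the chromosome merge into candidate regions.
    """
    tol = _stack(tolerant_profiles, tag_order)
    intol = _stack(intolerant_profiles, tag_order)
    if tol.shape[0] == 0 or intol.shape[0] == 0:
        raise ValueError("both pools must contain at least one sample")
    concord = tol.all(axis=0) & (~intol).all(axis=0)
    concord = pd.Series(concord, index=tag_order)

    regions = []
    i = 0
    while i < len(tag_order):
        if concord.iloc[i]:
            j = i
            while j + 1 < len(tag_order) and concord.iloc[j + 1]:
                j += 1
            run = tag_order[i:j + 1]
            chunks: list[str] = []
            if megachunk_of:
                for t in run:
                    c = megachunk_of.get(t, "")
                    if c and (not chunks or chunks[-1] != c):
                        chunks.append(c)
            regions.append((run[0], run[-1], chunks))
            i = j + 1
        else:
            i += 1
    return SegregationResult(regions=regions, concordance=concord)


def _stack(profiles, tag_order) -> np.ndarray:
    if isinstance(profiles, pd.DataFrame):
        profiles = [profiles]
    rows = []
    for p in profiles:
        rows.append(p.loc[tag_order, "syn"].to_numpy(dtype=bool))
    return np.array(rows) if rows else np.empty((0, len(tag_order)), dtype=bool)


def locate_common_junction(
    site_sets: list,
    min_strains: int = 2,
) -> list[tuple[int, int]]:
    """Rank loxPsym sites by how many strains' rearrangements use them.

    ``site_sets`` holds, per strain, the set of loxPsym site indices used by
    its called events (see :func:`callset_site_ids`).  Returns
    (site id, strain count) for sites used by at least ``min_strains``
    strains, most recurrent first.
    """
    if len(site_sets) < 2:
        raise ValueError("need callsets from at least two strains")
    counts: dict[int, int] = {}
    for s in site_sets:
        for site in set(s):
            counts[site] = counts.get(site, 0) + 1
    ranked = sorted(((site, c) for site, c in counts.items() if c >= min_strains),
                    key=lambda t: (-t[1], t[0]))
    return ranked


def callset_site_ids(callset, cmap: ChromosomeMap,
                     tolerance: int = 5) -> set[int]:
    """loxPsym site indices touched by a callset's junction breakends."""
    pos = cmap.site_positions
    out: set[int] = set()
    for j in getattr(callset, "junctions", callset):
        for bk in (j.bk1, j.bk2):
            if bk.chrom != cmap.name or len(pos) == 0:
                continue
            i = int(np.argmin(np.abs(pos - bk.locus)))
            if abs(int(pos[i]) - bk.locus) <= tolerance:
                out.add(i)
    return out


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_primers_tsv(path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    return [PrimerPair(name=r["name"], fwd=r["fwd"], rev=r["rev"],
                       max_product=int(r.get("max_product", 5000)),
                       tag_class=r.get("class", "junction"),
                       order=int(r.get("order", -1)),
                       megachunk=str(r.get("megachunk", "") or ""))
            for _, r in df.iterrows()]


def write_primers_tsv(path, pairs: list[PrimerPair]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tfwd\trev\tmax_product\tclass\torder\tmegachunk\n")
        for p in pairs:
            fh.write(f"{p.name}\t{p.fwd}\t{p.rev}\t{p.max_product}\t{p.tag_class}\t"
                     f"{p.order}\t{p.megachunk}\n")


def write_profile_tsv(path, profile: pd.DataFrame) -> None:
    profile.to_csv(path, sep="\t")
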