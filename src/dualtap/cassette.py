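"""In-silico model of the lox-3xHA-lox-V5 switchable tag cassette.

The donor oligo inserts, just before a bait gene's stop codon, a cassette of
two directly repeated lox sites flanking three HA epitope copies (with a stop
codon), followed by a short linker and a V5 epitope (with its own stop).
Before Cre the protein reads through the first lox into 3xHA and stops; Cre
excision collapses the two lox sites into one, and the single retained lox
(34 nt) plus the 2-nt linker — 36 nt, exactly 12 codons — keeps the V5 tag in
frame.

This module detects lox elements, simulates Cre excision, translates the tag
peptides, models a TaqI-family restriction digest, and carries the genotyping
amplicon arithmetic: with a knock-in PCR product of ``knockin_size`` bp, the
Cre-recombined ("turned") allele amplifies ``knockin_size - excised`` bp,
where ``excised`` is the lox-start-to-lox-start distance measured directly on
the donor sequence — arithmetic independent of the unprinted genomic flanks.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio.Seq import Seq
from Bio import SeqIO

#: 13-bp lox arms (the arm pair is its own reverse complement, so a single
#: forward-strand scan finds sites in either orientation; orientation is a
#: property of the asymmetric 8-bp spacer).
LOX_ARM5 = "ATAACTTCGTATA"
LOX_ARM3 = "TATACGAAGTTAT"
LOX_LENGTH = 34

#: the published 292-nt single-strand donor oligo for the RanBP9 turning
#: cassette (homology arms, lox-3xHA(stop)-lox, linker, V5(stop))
RANBP9_TURNX_SSODN = (
    "GGTCAGGAGTTGGGTCCTGTGCATTTGCCACAGTGGAAGACTACCTACAT"
    "ATAACTTCGTATAGCCTACATTATACGAAGTTAT"
    "CTTACCCATACGATGTTCCAGATTACGCTTACCCATACGATGTTCCAGATTACGCTTACCCATACGATGTTCCAGATTACGCTTAGC"
    "ATAACTTCGTATAGCCTACATTATACGAAGTTAT"
    "CTGGTAAGCCTATCCCTAACCCTCTCCTCGGTCTCGATTCTACGTAGCTATGCACTTCAAGAGCTCACACTCACATTGTGGCAAACA"
)

#: HA and V5 epitope peptides
HA_EPITOPE = "YPYDVPDYA"
V5_EPITOPE = "GKPIPNPLLGLDST"


class Orientation(str, Enum):
    FWD = "FWD"
    REV = "REV"


class CassetteError(ValueError):
    pass


def normalize(seq: str) -> str:
    s = "".join(seq.split()).upper()
    if not s:
        raise CassetteError("empty sequence")
    if not set(s) <= set("ACGT"):
        raise CassetteError(f"non-ACGT characters in sequence: {sorted(set(s) - set('ACGT'))}")
    return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class LoxSite:
    """One 34-bp lox element; ``start`` is 1-based inclusive."""

    start: int
    arm5: str
    spacer: str
    arm3: str
    orientation: Orientation = Orientation.FWD

    @property
    def end(self) -> int:
        return self.start + LOX_LENGTH - 1

    @property
    def sequence(self) -> str:
        return self.arm5 + self.spacer + self.arm3


@dataclass(frozen=True)
class AmpliconModel:
    """Printed genotyping anchors plus derived turned-allele sizes.

    Knock-in values default to the modelled genotyping assay: WT product
    256 bp, knock-in product 455 bp cut by TaqI (T^CGA) into 317 + 138 bp.
    """

    wt_size: int = 256
    knockin_size: int = 455
    enzyme_site: str = "TCGA"
    knockin_fragments: tuple[int, int] = (317, 138)

    def __post_init__(self) -> None:
        if sum(self.knockin_fragments) != self.knockin_size:
            raise CassetteError("knock-in fragments must sum to the knock-in amplicon size")

    def turned_fragments(self, excised: int) -> tuple[int, int]:
        """Fragment sizes of the turned amplicon: the cut site sits downstream
        of the excised segment, so only the larger fragment shrinks."""
        big = self.knockin_fragments[0] - excised
        if big <= 0:
            raise CassetteError("excised length exceeds the cut fragment")
        return (big, self.knockin_fragments[1])


def find_lox_sites(seq: str) -> list[LoxSite]:
    """All arm5 + N8 + arm3 matches on the given strand, sorted by start.

    Because the arm pair is reverse-complement symmetric, a forward scan also
    covers reverse-orientation sites; a site is reported REV when its spacer
    matches the reverse complement of another detected site's spacer but not
    that spacer itself (direct repeats share a spacer verbatim).
    """
    s = normalize(seq)
    pat = re.compile(f"(?=({LOX_ARM5})(.{{8}})({LOX_ARM3}))")
    sites = [
        LoxSite(start=m.start() + 1, arm5=m.group(1), spacer=m.group(2), arm3=m.group(3))
        for m in pat.finditer(s)
    ]
    if len(sites) == 2:
        s0, s1 = sites
        if s1.spacer != s0.spacer and s1.spacer == reverse_complement(s0.spacer):
            sites[1] = LoxSite(s1.start, s1.arm5, s1.spacer, s1.arm3, Orientation.REV)
    return sites


def lox_distance(sites: list[LoxSite]) -> int:
    """Start-to-start distance of a two-site cassette."""
    if len(sites) != 2:
        raise CassetteError(f"expected exactly 2 lox sites, found {len(sites)}")
    return sites[1].start - sites[0].start


def cre_excise(seq: str, sites: list[LoxSite] | None = None) -> str:
    """Simulate Cre excision between two directly repeated lox sites.

    Removes ``start(site1) .. start(site2) - 1``, leaving a single lox copy;
    the output is shorter by exactly the start-to-start distance.  Inverted
    site pairs (spacers that are reverse complements) and overlapping sites
    are rejected.
    """
    s = normalize(seq)
    if sites is None:
        sites = find_lox_sites(s)
    if len(sites) != 2:
        raise CassetteError(f"excision needs exactly 2 lox sites, found {len(sites)}")
    first, second = sorted(sites, key=lambda x: x.start)
    if first.spacer != second.spacer:
        if second.spacer == reverse_complement(first.spacer):
            raise CassetteError("inversion not supported: lox sites are inverted repeats")
        raise CassetteError("lox spacers differ: sites are incompatible")
    if second.start - first.start < LOX_LENGTH:
        raise CassetteError("overlapping lox sites")
    return s[: first.start - 1] + s[second.start - 1 :]


@dataclass(frozen=True)
class TagPeptide:
    """Translation product up to (not including) the first stop codon."""

    peptide: str
    complete: bool  #: False when no stop codon was reached ("open" reading)

    def __str__(self) -> str:
        return self.peptide


def translate_tag(seq: str, frame_offset: int = 0) -> TagPeptide:
    """Standard-genetic-code translation from ``frame_offset`` to the first stop."""
    if frame_offset not in (0, 1, 2):
        raise CassetteError("frame_offset must be 0, 1 or 2")
    s = normalize(seq)[frame_offset:]
    s = s[: len(s) - len(s) % 3]
    aa = str(Seq(s).translate())
    if "*" in aa:
        return TagPeptide(aa.split("*")[0], complete=True)
    return TagPeptide(aa, complete=False)


def digest(seq: str, recognition: str = "TCGA", cut_offset: int = 1) -> list[int]:
    """Fragment lengths after cutting at every recognition occurrence.

    The cut falls ``cut_offset`` bases into the site (TaqI convention T^CGA,
    offset 1).  Fragment lengths always sum to the sequence length.
    """
    s = normalize(seq)
    recognition = normalize(recognition)
    if len(recognition) < 4:
        raise CassetteError("recognition site must be at least 4 bases")
    if not 0 <= cut_offset <= len(recognition):
        raise CassetteError("cut_offset must lie within the recognition site")
    cuts = [m.start() + cut_offset for m in re.finditer(f"(?={recognition})", s)]
    cuts = [c for c in cuts if 0 < c < len(s)]
    bounds = [0, *cuts, len(s)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def turned_amplicon_size(model: AmpliconModel, excised: int) -> int:
    """Amplicon size of the recombined allele: knock-in size minus excision."""
    if excised >= model.knockin_size:
        raise CassetteError("excised length must be smaller than the knock-in amplicon")
    size = model.knockin_size - excised
    if size <= 0:
        raise CassetteError("nonpositive amplicon size")
    return size


def load_sequence(path: str | Path) -> str:
    """Read a single sequence from FASTA or plain text."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(path, "fasta"))
        if len(records) != 1:
            raise CassetteError(f"expected one FASTA record, found {len(records)}")
        return normalize(str(records[0].seq))
    return normalize(text)


def cassette_report(seq: str, model: AmpliconModel | None = None) -> dict:
    """Sites, excision arithmetic, tag translations and digest of a cassette."""
    s = normalize(seq)
    model = model or AmpliconModel()
    sites = find_lox_sites(s)
    report: dict = {
        "length": len(s),
        "lox_sites": [
            {"start": x.start, "spacer": x.spacer, "orientation": x.orientation.value}
            for x in sites
        ],
        "digest_fragments": digest(s, model.enzyme_site),
    }
    if len(sites) == 2 and sites[0].spacer == sites[1].spacer:
        d = lox_distance(sites)
        turned = cre_excise(s, sites)
        frame = (sites[0].start - 1) % 3
        report.update(
            {
                "excised_bp": d,
                "recombined_length": len(turned),
                "turned_amplicon_bp": turned_amplicon_size(model, d),
                "turned_fragments_bp": list(model.turned_fragments(d)),
                "tag_peptide_unrecombined": translate_tag(s[sites[0].start - 1 :]).peptide,
                "tag_peptide_recombined": translate_tag(turned[sites[0].start - 1 :]).peptide,
            }
        )
    return report
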