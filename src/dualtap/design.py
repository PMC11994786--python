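"""Experimental design vocabulary and sample sheets.

The study design is a fully crossed layout: ``n_couples`` matched pairs of
mice (one wild-type, one tagged), each mouse immunoprecipitated with anti-HA,
anti-V5 and isotype-control (Ig) beads in ``replicates_per_arm`` replicates.
With the study values (4 couples, 4 replicates) this gives
4 couples x 2 genotypes x 3 arms x 4 replicates = 96 IP fractions,
24 per couple.

Every downstream stage selects samples by declared ``(genotype, arm)`` group,
never by column order, so the sample sheet is the single source of truth for
which fraction belongs to which group.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class Genotype(str, Enum):
    """Mouse genotype: wild-type or carrying the switchable tag cassette."""

    WT = "WT"
    TURNX = "TURNX"


class Arm(str, Enum):
    """Immunoprecipitation arm: the antibody conjugated to the beads."""

    HA = "HA"
    V5 = "V5"
    IG = "IG"


#: A sample group: one (genotype, arm) cell of the design.
Group = tuple[Genotype, Arm]

SHEET_COLUMNS = ("sample_id", "mouse_id", "couple_id", "genotype", "arm", "replicate")


class SampleSheetError(ValueError):
    """Raised when a sample sheet fails validation."""


@dataclass(frozen=True)
class SampleRecord:
    """One immunoprecipitated fraction.

    Parameters
    ----------
    sample_id : str
        Unique identifier of the fraction within the sheet.
    mouse_id : str
        Identifier of the animal the lysate came from.
    couple_id : str
        Identifier of the matched WT/tagged pair the animal belongs to.
    genotype : Genotype
    arm : Arm
    replicate : int
        1-based replicate index within the (mouse, arm) cell.
    """

    sample_id: str
    mouse_id: str
    couple_id: str
    genotype: Genotype
    arm: Arm
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise SampleSheetError(
                f"replicate must be a positive integer, got {self.replicate!r} "
                f"for sample {self.sample_id!r}"
            )

    @property
    def group(self) -> Group:
        return (self.genotype, self.arm)


@dataclass(frozen=True)
class StudyDesign:
    """The crossed couples x genotypes x arms x replicates layout.

    Defaults are the study values: 4 couples, 4 replicates per arm.
    """

    n_couples: int = 4
    replicates_per_arm: int = 4
    arms: tuple[Arm, ...] = (Arm.HA, Arm.V5, Arm.IG)
    genotypes: tuple[Genotype, ...] = (Genotype.WT, Genotype.TURNX)

    def __post_init__(self) -> None:
        if self.n_couples < 1 or self.replicates_per_arm < 1:
            raise ValueError("n_couples and replicates_per_arm must be positive")
        if len(set(self.arms)) != len(self.arms) or len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("arms and genotypes must not repeat")

    @property
    def n_mice(self) -> int:
        return self.n_couples * len(self.genotypes)

    @property
    def samples_per_couple(self) -> int:
        return len(self.genotypes) * len(self.arms) * self.replicates_per_arm

    @property
    def total_samples(self) -> int:
        return self.n_couples * self.samples_per_couple


@dataclass(frozen=True)
class ContrastSpec:
    """A case group tested against three negative-control groups.

    For tag HA the case is (TURNX, HA) and the controls are the same beads on
    untagged lysate plus the isotype beads on both genotypes:
    ``[(WT, HA), (TURNX, IG), (WT, IG)]``; the V5 contrast is analogous.
    """

    tag: Arm
    case_group: Group
    control_groups: tuple[Group, Group, Group]

    def __post_init__(self) -> None:
        if self.tag not in (Arm.HA, Arm.V5):
            raise ValueError(f"tag must be HA or V5, got {self.tag}")
        if len(self.control_groups) != 3:
            raise ValueError("exactly three control groups are required")
        if self.case_group != (Genotype.TURNX, self.tag):
            raise ValueError("case group must be (TURNX, <tag arm>)")


def default_contrasts() -> list[ContrastSpec]:
    """The two per-tag contrasts, each with its three negative-control groups."""
    out = []
    for tag in (Arm.HA, Arm.V5):
        out.append(
            ContrastSpec(
                tag=tag,
                case_group=(Genotype.TURNX, tag),
                control_groups=(
                    (Genotype.WT, tag),
                    (Genotype.TURNX, Arm.IG),
                    (Genotype.WT, Arm.IG),
                ),
            )
        )
    return out


def build_sample_records(design: StudyDesign) -> list[SampleRecord]:
    """Enumerate the sample sheet implied by a :class:`StudyDesign`.

    Identifiers are deterministic: couples ``c1..cN``, mice ``<couple>_<geno>``,
    samples ``<mouse>_<arm>_r<rep>``.
    """
    records: list[SampleRecord] = []
    for c in range(1, design.n_couples + 1):
        couple = f"c{c}"
        for geno in design.genotypes:
            mouse = f"{couple}_{geno.value.lower()}"
            for arm in design.arms:
                for rep in range(1, design.replicates_per_arm + 1):
                    records.append(
                        SampleRecord(
                            sample_id=f"{mouse}_{arm.value.lower()}_r{rep}",
                            mouse_id=mouse,
                            couple_id=couple,
                            genotype=geno,
                            arm=arm,
                            replicate=rep,
                        )
                    )
    return records


def _parse_enum(cls, token: str, row: int, what: str):
    try:
        return cls(token.strip().upper())
    except ValueError:
        raise SampleSheetError(
            f"unknown {what} {token!r} in sample sheet row {row}"
        ) from None


def load_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a TSV sample sheet into validated :class:`SampleRecord` rows.

    The sheet is UTF-8 TSV with header
    ``sample_id  mouse_id  couple_id  genotype  arm  replicate``;
    lines starting with ``#`` are ignored.  Genotype and arm tokens are
    case-normalized.  Duplicate sample ids and unknown enum tokens raise
    :class:`SampleSheetError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != list(SHEET_COLUMNS):
        raise SampleSheetError(
            f"sample sheet header must be {SHEET_COLUMNS}, got {reader.fieldnames}"
        )
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):
        sid = row["sample_id"].strip()
        if sid in seen:
            raise SampleSheetError(f"duplicate sample_id {sid!r} in sample sheet")
        seen.add(sid)
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise SampleSheetError(
                f"replicate must be an integer, got {row['replicate']!r} in row {i}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=sid,
                mouse_id=row["mouse_id"].strip(),
                couple_id=row["couple_id"].strip(),
                genotype=_parse_enum(Genotype, row["genotype"], i, "genotype"),
                arm=_parse_enum(Arm, row["arm"], i, "arm"),
                replicate=rep,
            )
        )
    return records


def write_sample_sheet(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write records as the TSV sheet read back by :func:`load_sample_sheet`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SHEET_COLUMNS)
        for r in records:
            writer.writerow(
                [r.sample_id, r.mouse_id, r.couple_id, r.genotype.value, r.arm.value, r.replicate]
            )


def samples_in_group(records: Sequence[SampleRecord], group: Group) -> list[SampleRecord]:
    """All records whose (genotype, arm) equals ``group``."""
    return [r for r in records if r.group == group]


def validate_design_complete(records: Sequence[SampleRecord], design: StudyDesign) -> None:
    """Check a sheet against a design: counts and WT/TURNX pairing per couple.

    Raises :class:`SampleSheetError` on the first violation.
    """
    if len(records) != design.total_samples:
        raise SampleSheetError(
            f"expected {design.total_samples} samples for the design, got {len(records)}"
        )
    for r in records:
        if r.replicate > design.replicates_per_arm:
            raise SampleSheetError(
                f"replicate {r.replicate} of sample {r.sample_id!r} exceeds "
                f"replicates_per_arm={design.replicates_per_arm}"
            )
    couples: dict[str, set[tuple[str, Genotype]]] = {}
    for r in records:
        couples.setdefault(r.couple_id, set()).add((r.mouse_id, r.genotype))
    for couple, mice in couples.items():
        genos = sorted(g.value for _, g in mice)
        if len(mice) != 2 or genos != ["TURNX", "WT"]:
            raise SampleSheetError(
                f"couple {couple!r} must contain exactly one WT and one TURNX mouse"
            )
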