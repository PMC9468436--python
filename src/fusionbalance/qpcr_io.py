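"""Reading, writing and validating qPCR cycle-threshold (Ct) tables.

Conventions used throughout the package:

* A PCR run comprises 38 cycles.  A reaction with no detectable
  amplification curve by the final cycle is recorded as *censored at
  Ct = 38*: the true Ct is unknown but at least 38, so 38 acts as a
  conservative bound in all downstream arithmetic.
* Sample quality is gated on the reference gene SDHA: a sample is
  evaluable only when its SDHA reaction crosses threshold strictly
  before cycle 36.
* Fusion breakpoints are written in the field's junction notation,
  e.g. ``EML4-ALK (E13;A20)`` — EML4 exon 13 joined to ALK exon 20 —
  with optional insertion/deletion modifiers such as ``E6ins33``.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "CENSOR_CT",
    "QC_MAX_REFERENCE_CT",
    "CtValue",
    "Assay",
    "Panel",
    "DEFAULT_PANEL",
    "FusionVariant",
    "SampleRecord",
    "InvalidMeasurementError",
    "PanelConfigError",
    "FusionNameError",
    "CtTableError",
    "BreakpointLetterWarning",
    "cap_ct",
    "qc_evaluable",
    "parse_fusion_name",
    "read_ct_table",
    "write_ct_table",
    "load_panel",
]

#: Final PCR cycle; undetected reactions are censored at this value.
CENSOR_CT = 38.0
#: A sample passes QC only if SDHA crosses threshold strictly before this cycle.
QC_MAX_REFERENCE_CT = 36.0

DRIVER_STATUSES = ("EGFR", "ALK", "ROS1", "MET_ex14", "KRAS", "NRAS", "none", "unknown")


class InvalidMeasurementError(ValueError):
    """A raw Ct outside the physically meaningful range (0, 38]."""


class PanelConfigError(ValueError):
    """The assay panel and the data disagree (missing reference, unknown assay...)."""


class FusionNameError(ValueError):
    """A fusion-variant string that cannot be parsed."""


class CtTableError(ValueError):
    """A malformed Ct table (duplicate ids, non-numeric cells, bad columns)."""


class BreakpointLetterWarning(UserWarning):
    """Breakpoint letter does not match the initial of the flanking gene symbol."""


@dataclass(frozen=True)
class CtValue:
    """A possibly-censored cycle threshold.

    ``censored`` is True when no curve was detected within the run (or
    detection occurred exactly at the final cycle); ``cycles`` is then the
    bound 38, not an estimate.
    """

    cycles: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.cycles <= CENSOR_CT):
            raise InvalidMeasurementError(
                f"Ct must lie in (0, {CENSOR_CT:g}], got {self.cycles!r}"
            )
        if self.censored and self.cycles != CENSOR_CT:
            raise InvalidMeasurementError(
                f"censored Ct must equal {CENSOR_CT:g}, got {self.cycles!r}"
            )


def cap_ct(raw: Optional[float]) -> CtValue:
    """Convert a raw instrument Ct into a :class:`CtValue`.

    An absent measurement (no detectable curve) or a reading at the final
    cycle is censored at 38; anything else passes through unchanged.
    Values outside (0, 38] raise :class:`InvalidMeasurementError`.
    """
    if raw is None:
        return CtValue(CENSOR_CT, censored=True)
    raw = float(raw)
    if not (0.0 < raw <= CENSOR_CT):
        raise InvalidMeasurementError(f"Ct must lie in (0, {CENSOR_CT:g}], got {raw!r}")
    if raw == CENSOR_CT:
        return CtValue(CENSOR_CT, censored=True)
    return CtValue(raw, censored=False)


# ---------------------------------------------------------------------------
# Assay panel


@dataclass(frozen=True)
class Assay:
    """One qPCR assay of the panel: a gene, an amplicon exon span and a role."""

    name: str
    gene: str
    role: str  # 'reference' | 'five_prime' | 'three_prime'
    exon_start: Optional[int] = None
    exon_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ("reference", "five_prime", "three_prime"):
            raise PanelConfigError(f"unknown assay role {self.role!r} for {self.name}")


@dataclass(frozen=True)
class Panel:
    """The declared set of assays of a Ct table.

    Exactly one assay must have the ``reference`` role; every gene with a
    3'-end assay needs at least one 5'-end assay so that an imbalance
    statistic can be formed.
    """

    assays: tuple[Assay, ...]

    def __post_init__(self) -> None:
        refs = [a for a in self.assays if a.role == "reference"]
        if len(refs) != 1:
            raise PanelConfigError(f"panel must declare exactly one reference assay, got {len(refs)}")
        names = [a.name for a in self.assays]
        if len(set(names)) != len(names):
            raise PanelConfigError("duplicate assay names in panel")
        for gene in {a.gene for a in self.assays if a.role == "three_prime"}:
            if not any(a.gene == gene and a.role == "five_prime" for a in self.assays):
                raise PanelConfigError(f"gene {gene} has a 3' assay but no 5' assay")

    @property
    def reference(self) -> Assay:
        return next(a for a in self.assays if a.role == "reference")

    @property
    def assay_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.assays)

    def __getitem__(self, name: str) -> Assay:
        for a in self.assays:
            if a.name == name:
                return a
        raise KeyError(name)

    def pairs(self) -> tuple[tuple[str, str], ...]:
        """All (5'-assay, 3'-assay) pairs, per gene, in panel order."""
        out = []
        for three in self.assays:
            if three.role != "three_prime":
                continue
            for five in self.assays:
                if five.role == "five_prime" and five.gene == three.gene:
                    out.append((five.name, three.name))
        return tuple(out)


#: The ALK/ROS1 screening panel: SDHA reference, two ALK 5' amplicons
#: (exons 9-10 and 19-20), the ALK kinase-domain amplicon (exons 22-23),
#: and one ROS1 amplicon per end (exons 17-18 and 38-39).
DEFAULT_PANEL = Panel(
    (
        Assay("SDHA", "SDHA", "reference"),
        Assay("ALK_ex9_10", "ALK", "five_prime", 9, 10),
        Assay("ALK_ex19_20", "ALK", "five_prime", 19, 20),
        Assay("ALK_ex22_23", "ALK", "three_prime", 22, 23),
        Assay("ROS1_ex17_18", "ROS1", "five_prime", 17, 18),
        Assay("ROS1_ex38_39", "ROS1", "three_prime", 38, 39),
    )
)


def load_panel(path: str | Path) -> Panel:
    """Load a panel from YAML: a list of {name, gene, role, exon_start, exon_end}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise PanelConfigError("panel YAML must be a list of assay mappings")
    assays = tuple(
        Assay(
            name=entry["name"],
            gene=entry["gene"],
            role=entry["role"],
            exon_start=entry.get("exon_start"),
            exon_end=entry.get("exon_end"),
        )
        for entry in raw
    )
    return Panel(assays)


# ---------------------------------------------------------------------------
# Fusion-variant nomenclature

_DASHES = "‐‑‒–—―−"  # unicode hyphens/dashes
_MOD = r"(?:ins|del)\d+"
_NAME_RE = re.compile(
    r"^\s*(?P<g5>[A-Za-z0-9]+)-(?P<g3>[A-Za-z0-9]+)\s*"
    r"\(\s*(?P<side5>[^;()]+);(?P<side3>[^;()]+)\s*\)\s*$"
)
_SIDE5_RE = re.compile(rf"^(?P<letter>[A-Za-z])(?P<exon>\d+)(?P<mods>(?:{_MOD})*)$")
_SIDE3_RE = re.compile(rf"^(?P<mods>(?:{_MOD})*)(?P<letter>[A-Za-z])(?P<exon>\d+)$")
_MOD_RE = re.compile(_MOD)


@dataclass(frozen=True)
class FusionVariant:
    """A fusion transcript breakpoint, e.g. EML4 exon 13 joined to ALK exon 20.

    Modifiers record small insertions/deletions at the junction and keep
    their side of the breakpoint, so the canonical string form round-trips.
    """

    five_prime_gene: str
    three_prime_gene: str
    five_prime_exon: int
    three_prime_exon: int
    five_prime_modifiers: tuple[str, ...] = ()
    three_prime_modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.five_prime_exon < 1 or self.three_prime_exon < 1:
            raise FusionNameError("exon numbers must be >= 1")

    @property
    def modifiers(self) -> tuple[str, ...]:
        return self.five_prime_modifiers + self.three_prime_modifiers

    def canonical_name(self) -> str:
        side5 = (
            f"{self.five_prime_gene[0]}{self.five_prime_exon}"
            + "".join(self.five_prime_modifiers)
        )
        side3 = (
            "".join(self.three_prime_modifiers)
            + f"{self.three_prime_gene[0]}{self.three_prime_exon}"
        )
        return f"{self.five_prime_gene}-{self.three_prime_gene} ({side5};{side3})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name()


def parse_fusion_name(text: str) -> FusionVariant:
    """Parse junction notation like ``"EML4-ALK (E13;A20)"``.

    Unicode dashes are normalised to ASCII hyphens.  The single letter
    before each exon number must be the initial of the flanking gene
    symbol; a mismatch emits :class:`BreakpointLetterWarning` (published
    tables occasionally carry such slips) but still parses.
    """
    norm = text
    for d in _DASHES:
        norm = norm.replace(d, "-")
    m = _NAME_RE.match(norm)
    if m is None:
        raise FusionNameError(f"cannot parse fusion name {text!r}")
    g5, g3 = m.group("g5"), m.group("g3")
    m5 = _SIDE5_RE.match(m.group("side5").strip())
    if m5 is None:
        raise FusionNameError(
            f"cannot parse 5' breakpoint token {m.group('side5').strip()!r} in {text!r}"
        )
    m3 = _SIDE3_RE.match(m.group("side3").strip())
    if m3 is None:
        raise FusionNameError(
            f"cannot parse 3' breakpoint token {m.group('side3').strip()!r} in {text!r}"
        )
    for letter, gene in ((m5.group("letter"), g5), (m3.group("letter"), g3)):
        if letter.upper() != gene[0].upper():
            warnings.warn(
                f"breakpoint letter {letter!r} does not match gene {gene!r} in {text!r}",
                BreakpointLetterWarning,
                stacklevel=2,
            )
    return FusionVariant(
        five_prime_gene=g5,
        three_prime_gene=g3,
        five_prime_exon=int(m5.group("exon")),
        three_prime_exon=int(m3.group("exon")),
        five_prime_modifiers=tuple(_MOD_RE.findall(m5.group("mods"))),
        three_prime_modifiers=tuple(_MOD_RE.findall(m3.group("mods"))),
    )


# ---------------------------------------------------------------------------
# Sample records and tables


@dataclass(frozen=True)
class SampleRecord:
    """One tumour sample: panel Cts, variant-specific PCR calls, covariates."""

    sample_id: str
    ct: Mapping[str, CtValue]
    variant_calls: tuple[FusionVariant, ...] = ()
    driver_status: Optional[str] = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def with_calls(self, calls: Sequence[FusionVariant]) -> "SampleRecord":
        return replace(self, variant_calls=tuple(calls))


def qc_evaluable(sample: SampleRecord, panel: Panel = DEFAULT_PANEL) -> bool:
    """True iff the sample's reference-gene Ct is uncensored and < 36.

    The gate is strict — a signal appearing *at* cycle 36 fails — and a
    censored reference (no curve at all) always fails.
    """
    ref = panel.reference.name
    if ref not in sample.ct:
        raise PanelConfigError(f"sample {sample.sample_id} has no {ref} measurement")
    ct = sample.ct[ref]
    return (not ct.censored) and ct.cycles < QC_MAX_REFERENCE_CT


_META_COLUMNS = ("variant_call", "driver_status", "age", "sex", "smoking")
#: Separator between multiple variant calls in one CSV cell (';' is taken
#: by the breakpoint notation itself).
CALL_SEPARATOR = "|"


def read_ct_table(path: str | Path, panel: Panel = DEFAULT_PANEL) -> list[SampleRecord]:
    """Read a Ct table CSV into :class:`SampleRecord` objects.

    Expected columns: ``sample_id``, one column per panel assay, and
    optionally ``variant_call`` (canonical fusion strings, several joined
    by ``|``), ``driver_status``, ``age``, ``sex``, ``smoking``.  Empty Ct
    cells mean "no curve detected" and are censored at 38.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CtTableError(f"{path}: empty file")
        cols = list(reader.fieldnames)
        if "sample_id" not in cols:
            raise CtTableError(f"{path}: missing required column 'sample_id'")
        known = {"sample_id", *panel.assay_names, *_META_COLUMNS}
        unknown = [c for c in cols if c not in known]
        if unknown:
            raise CtTableError(f"{path}: unknown column(s) {unknown!r} not in panel")
        missing = [a for a in panel.assay_names if a not in cols]
        if missing:
            raise CtTableError(f"{path}: missing assay column(s) {missing!r}")

        records: list[SampleRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise CtTableError(f"{path}, row {i}: empty sample_id")
            if sid in seen:
                raise CtTableError(f"{path}, row {i}: duplicate sample_id {sid!r}")
            seen.add(sid)
            ct: dict[str, CtValue] = {}
            for assay in panel.assay_names:
                cell = (row.get(assay) or "").strip()
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    ct[assay] = cap_ct(None)
                else:
                    try:
                        raw = float(cell)
                    except ValueError:
                        raise CtTableError(
                            f"{path}, row {i}: non-numeric Ct {cell!r} in column {assay}"
                        ) from None
                    try:
                        ct[assay] = cap_ct(raw)
                    except InvalidMeasurementError as exc:
                        raise CtTableError(f"{path}, row {i}: {exc}") from None
            calls: tuple[FusionVariant, ...] = ()
            cell = (row.get("variant_call") or "").strip()
            if cell:
                calls = tuple(
                    parse_fusion_name(tok) for tok in cell.split(CALL_SEPARATOR) if tok.strip()
                )
            driver = (row.get("driver_status") or "").strip() or None
            cov: dict[str, object] = {}
            age = (row.get("age") or "").strip()
            if age:
                cov["age"] = float(age)
            for key in ("sex", "smoking"):
                val = (row.get(key) or "").strip()
                if val:
                    cov[key] = val
            records.append(
                SampleRecord(sid, ct, variant_calls=calls, driver_status=driver, covariates=cov)
            )
    return records


def _format_ct(ct: CtValue) -> str:
    if ct.censored:
        return ""  # empty cell = no curve; round-trips to censored-at-38
    return repr(ct.cycles)


def write_ct_table(
    samples: Iterable[SampleRecord], path: str | Path, panel: Panel = DEFAULT_PANEL
) -> None:
    """Write samples back to the CSV layout :func:`read_ct_table` accepts."""
    path = Path(path)
    cols = ["sample_id", *panel.assay_names, *_META_COLUMNS]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for s in samples:
            row: list[str] = [s.sample_id]
            for assay in panel.assay_names:
                row.append(_format_ct(s.ct[assay]) if assay in s.ct else "")
            row.append(CALL_SEPARATOR.join(v.canonical_name() for v in s.variant_calls))
            row.append(s.driver_status or "")
            age = s.covariates.get("age")
            row.append("" if age is None else repr(float(age)))
            row.append(str(s.covariates.get("sex") or ""))
            row.append(str(s.covariates.get("smoking") or ""))
            writer.writerow(row)
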