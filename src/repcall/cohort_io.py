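"""Cohort data model and delimited-text I/O.

A *cohort* is a list of screened subjects, each carrying the Ct values of
one or more replicate PCR reactions for the methylation target and for the
ACTB internal control. A reaction that never crossed the fluorescence
threshold within the run is *undetected*; this state is carried by an
explicit sentinel (:data:`UNDETECTED`), never by a magic numeric Ct, so it
cannot collide with a real measurement. The numeric stand-in 45 appears
only downstream, when ROC analysis explicitly censors undetected wells to
the cycle ceiling.

File format
-----------
UTF-8 delimited text (comma or tab, autodetected), one row per subject::

    subject_id,group,stage,sex,age_band,target_ct_1..n,control_ct_1..n

``group`` is one of CRC, ADENOMA, POLYPS, IBD, OTHER_GI, NED; ``stage`` is
0/I/II/III/IV/NOT_SPECIFIED for CRC and NA otherwise. Undetected wells are
written as the literal token ``ND``. Ct values carry up to two decimals.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Union

import yaml

from .errors import CohortParseError, ConfigError, ValidationError

logger = logging.getLogger(__name__)

#: File token for an undetected (no-amplification) well.
ND_TOKEN = "ND"


class _UndetectedType:
    """Singleton sentinel for a well with no Ct (no amplification)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDETECTED"

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: The undetected sentinel. Compare with ``is UNDETECTED``.
UNDETECTED = _UndetectedType()

#: A Ct value: PCR cycles (positive float) or the undetected sentinel.
Ct = Union[float, _UndetectedType]


def is_detected(ct: Ct) -> bool:
    """True if ``ct`` is a numeric cycle value rather than UNDETECTED."""
    return ct is not UNDETECTED


class Group(str, Enum):
    """Diagnostic group of a screened subject."""

    CRC = "CRC"
    ADENOMA = "ADENOMA"
    POLYPS = "POLYPS"
    IBD = "IBD"
    OTHER_GI = "OTHER_GI"
    NED = "NED"


class Stage(str, Enum):
    """CRC stage; NA for every non-CRC subject."""

    S0 = "0"
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    NOT_SPECIFIED = "NOT_SPECIFIED"
    NA = "NA"


#: Canonical ordering used for deterministic iteration and reports.
GROUP_ORDER = [Group.CRC, Group.ADENOMA, Group.POLYPS, Group.IBD,
               Group.OTHER_GI, Group.NED]
CRC_STAGES = [Stage.S0, Stage.I, Stage.II, Stage.III, Stage.IV,
              Stage.NOT_SPECIFIED]


@dataclass(frozen=True)
class ReplicateMeasurement:
    """One PCR well: methylation-target Ct, ACTB control Ct, well index."""

    target_ct: Ct
    control_ct: Ct
    replicate_index: int

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1, got {self.replicate_index}")
        for name in ("target_ct", "control_ct"):
            v = getattr(self, name)
            if is_detected(v) and not (float(v) > 0):
                raise ValidationError(f"{name} must be positive, got {v!r}")


@dataclass(frozen=True)
class AssayConfig:
    """Assay geometry and interpretation thresholds.

    Parameters
    ----------
    n_replicates : int
        PCR wells per subject (3 for the triplicate assay, 1 for the
        single-well assay).
    k_required : int
        Positives required among the n wells for a positive subject call.
    ct_cutoff : float
        A detected target Ct <= this value is a positive well (ties at the
        cutoff count as positive).
    max_cycles : float
        Cycles run; the censoring ceiling used in ROC analysis.
    pcr_input_volume_ul : float
        Microlitres of eluate template placed in one reaction.
    plasma_equivalent_ml : float
        Millilitres of original plasma represented by one reaction; the
        scaling currency for volume-based performance prediction.
    """

    n_replicates: int
    k_required: int
    ct_cutoff: float
    max_cycles: float
    pcr_input_volume_ul: float
    plasma_equivalent_ml: float
    name: str = "custom"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 1 <= self.k_required <= self.n_replicates:
            raise ConfigError(
                f"k_required must be in [1, {self.n_replicates}], "
                f"got {self.k_required}")
        if not 0 < self.ct_cutoff <= self.max_cycles:
            raise ConfigError("require 0 < ct_cutoff <= max_cycles")
        if self.plasma_equivalent_ml <= 0:
            raise ConfigError("plasma_equivalent_ml must be > 0")
        if self.pcr_input_volume_ul <= 0:
            raise ConfigError("pcr_input_volume_ul must be > 0")


#: Named assay presets. The triplicate assay runs 45 cycles with a cutoff at
#: the ceiling; the single-well, doubled-template assay trades its larger
#: reaction volume for an earlier cutoff (41) to hold specificity.
ASSAY_PRESETS: Mapping[str, AssayConfig] = {
    "epi_procolon_2": AssayConfig(
        n_replicates=3, k_required=2, ct_cutoff=45.0, max_cycles=45.0,
        pcr_input_volume_ul=15.0, plasma_equivalent_ml=0.9,
        name="epi_procolon_2"),
    "sensicolon": AssayConfig(
        n_replicates=1, k_required=1, ct_cutoff=41.0, max_cycles=45.0,
        pcr_input_volume_ul=30.0, plasma_equivalent_ml=1.8,
        name="sensicolon"),
}


def load_assay_config(source: str | Path) -> AssayConfig:
    """Resolve an assay from a preset name or a YAML config file.

    The YAML file carries an ``assay`` block mirroring the
    :class:`AssayConfig` fields (an ``assay: <preset-name>`` string is also
    accepted).
    """
    if isinstance(source, str) and source in ASSAY_PRESETS:
        return ASSAY_PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise ConfigError(
            f"unknown assay preset or missing config file: {source!r} "
            f"(presets: {sorted(ASSAY_PRESETS)})")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "assay" not in doc:
        raise ConfigError(f"{path}: config must contain an 'assay' block")
    block = doc["assay"]
    if isinstance(block, str):
        if block not in ASSAY_PRESETS:
            raise ConfigError(f"{path}: unknown assay preset {block!r}")
        return ASSAY_PRESETS[block]
    try:
        return AssayConfig(**block)
    except TypeError as exc:
        raise ConfigError(f"{path}: bad assay block: {exc}") from None


@dataclass(frozen=True)
class SubjectRecord:
    """One screened subject with their replicate PCR measurements."""

    subject_id: str
    group: Group
    stage: Stage
    replicates: tuple[ReplicateMeasurement, ...]
    sex: str = ""
    age_band: str = ""

    def __post_init__(self):
        object.__setattr__(self, "replicates", tuple(self.replicates))
        if (self.stage != Stage.NA) != (self.group == Group.CRC):
            raise ValidationError(
                f"subject {self.subject_id!r}: stage must be NA iff group "
                f"is not CRC (group={self.group.value}, "
                f"stage={self.stage.value})")


@dataclass
class Cohort:
    """An ordered collection of subjects measured under one assay."""

    subjects: list[SubjectRecord]
    assay: AssayConfig
    provenance: str = ""

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)

    def group_counts(self) -> dict[Group, int]:
        counts: dict[Group, int] = {}
        for s in self.subjects:
            counts[s.group] = counts.get(s.group, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# delimited-text reading / writing
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["subject_id", "group", "stage", "sex", "age_band"]


def _columns(n: int) -> list[str]:
    return (_FIXED_COLUMNS
            + [f"target_ct_{i}" for i in range(1, n + 1)]
            + [f"control_ct_{i}" for i in range(1, n + 1)])


def _parse_ct(token: str, where: str) -> Ct:
    token = token.strip()
    if token == ND_TOKEN:
        return UNDETECTED
    try:
        value = float(token)
    except ValueError:
        raise CohortParseError(
            f"{where}: Ct value {token!r} is neither numeric nor "
            f"the undetected token {ND_TOKEN!r}") from None
    return value


def _format_ct(ct: Ct) -> str:
    if ct is UNDETECTED:
        return ND_TOKEN
    return f"{float(ct):.2f}"


def read_cohort(path: str | Path, assay: AssayConfig) -> Cohort:
    """Read a cohort file (comma- or tab-delimited; see module docstring).

    Raises
    ------
    ConfigError
        Missing required columns for the assay's replicate count.
    CohortParseError
        Non-numeric Ct other than the ``ND`` token, naming the row.
    ValidationError
        Unknown group/stage labels, stage/group inconsistency, duplicate
        subject ids, or a detected target Ct outside (0, max_cycles].
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    # leading "# provenance:" comment lines carry simulation metadata
    comment = ""
    while lines and lines[0].startswith("#"):
        comment = lines.pop(0).lstrip("# ").removeprefix("provenance: ")
    if not lines:
        raise ConfigError(f"{path}: no header row")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(_io.StringIO("\n".join(lines)),
                            delimiter=delimiter)
    required = _columns(assay.n_replicates)
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")

    header_offset = 2 + (1 if comment else 0)
    subjects: list[SubjectRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(reader, start=header_offset):
        where = f"{path}:{lineno}"
        sid = (row["subject_id"] or "").strip()
        if not sid:
            raise ValidationError(f"{where}: empty subject_id")
        if sid in seen:
            raise ValidationError(f"{where}: duplicate subject_id {sid!r}")
        seen.add(sid)
        try:
            group = Group(row["group"].strip())
        except ValueError:
            raise ValidationError(
                f"{where}: unknown group {row['group']!r}; allowed: "
                f"{[g.value for g in Group]}") from None
        try:
            stage = Stage(row["stage"].strip())
        except ValueError:
            raise ValidationError(
                f"{where}: unknown stage {row['stage']!r}; allowed: "
                f"{[s.value for s in Stage]}") from None
        reps = []
        for i in range(1, assay.n_replicates + 1):
            t = _parse_ct(row[f"target_ct_{i}"], where)
            c = _parse_ct(row[f"control_ct_{i}"], where)
            if is_detected(t) and not (0 < float(t) <= assay.max_cycles):
                raise ValidationError(
                    f"{where}: target_ct_{i}={t} outside "
                    f"(0, {assay.max_cycles}]")
            reps.append(ReplicateMeasurement(t, c, i))
        subjects.append(SubjectRecord(
            subject_id=sid, group=group, stage=stage,
            replicates=tuple(reps),
            sex=(row["sex"] or "").strip(),
            age_band=(row["age_band"] or "").strip()))

    provenance = f"{path} ({comment})" if comment else str(path)
    cohort = Cohort(subjects=subjects, assay=assay, provenance=provenance)
    counts = {g.value: n for g, n in cohort.group_counts().items()}
    logger.info("read %d subjects from %s (groups: %s)",
                len(subjects), path, counts)
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort file; ``read_cohort`` of the result round-trips.

    Undetected wells are written as the ``ND`` token; Ct values are written
    with two decimals. A non-empty provenance (e.g. the simulation seed) is
    preserved as a leading ``# provenance:`` comment line.
    """
    path = Path(path)
    n = cohort.assay.n_replicates
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if cohort.provenance:
            fh.write(f"# provenance: {cohort.provenance}\n")
        writer = csv.writer(fh)
        writer.writerow(_columns(n))
        for s in cohort.subjects:
            if len(s.replicates) != n:
                raise ValidationError(
                    f"subject {s.subject_id!r} has {len(s.replicates)} "
                    f"replicates; assay expects {n}")
            row = [s.subject_id, s.group.value, s.stage.value, s.sex,
                   s.age_band]
            row += [_format_ct(m.target_ct) for m in s.replicates]
            row += [_format_ct(m.control_ct) for m in s.replicates]
            writer.writerow(row)
    logger.info("wrote %d subjects to %s", len(cohort.subjects), path)


# ---------------------------------------------------------------------------
# printed count-table fixtures
# ---------------------------------------------------------------------------

def load_printed_fixture(name: str):
    """Return one of the published count tables (``table2`` .. ``table5``).

    The returned mapping is keyed ``(row_label, column_label)`` ->
    :class:`~repcall.printed_tables.FixtureCell` holding the positive and
    total counts (ground truth) and the percentage as printed (which in two
    documented cells disagrees with its own counts at 1-decimal rounding).
    """
    from . import printed_tables
    tables = {
        "table2": printed_tables.TABLE2,
        "table3": printed_tables.TABLE3,
        "table4": printed_tables.TABLE4,
        "table5": printed_tables.TABLE5,
    }
    if name not in tables:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(tables)}")
    return dict(tables[name])
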