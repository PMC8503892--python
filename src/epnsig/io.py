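"""Readers and writers for the pipeline's file formats.

Three kinds of input feed the classification pipeline:

* **RCC lane files** — the sectioned text format an nCounter instrument
  writes per lane: bracketed ``<Header>``, ``<Sample_Attributes>``,
  ``<Lane_Attributes>`` and ``<Code_Summary>`` sections, the last holding
  ``CodeClass,Name,Accession,Count`` rows for positive/negative controls,
  housekeeping genes and endogenous probes.
* **Expression-matrix TSV** — probes x samples, a header row of sample ids,
  an optional ``#scale=log2`` metadata line, and an optional two-column
  sample-label file mapping samples to tumour entities.
* **Clinical CSV** — one row per patient with age, sex, molecular group,
  fusion call and follow-up columns, mirroring the published
  supratentorial-cohort table. A 15-patient fixture ships with the package
  (:func:`load_table2`).

All downstream modules consume only the domain types defined here.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RccRecord",
    "RccLane",
    "ExpressionMatrix",
    "ClinicalRecord",
    "RccFormatError",
    "ClinicalFormatError",
    "read_rcc",
    "write_rcc",
    "read_rcc_batch",
    "write_rcc_batch",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "load_table2",
    "read_assignments",
    "write_assignments",
]

CODE_CLASSES = ("Positive", "Negative", "Housekeeping", "Endogenous")

#: Sentinel strings treated as "missing" in clinical tables.
_MISSING = {"", "-", "–", "—", "na", "n/a", "none"}


class RccFormatError(ValueError):
    """Malformed RCC lane file."""


class ClinicalFormatError(ValueError):
    """Malformed clinical table."""


class RccRecord(NamedTuple):
    code_class: str
    gene_name: str
    accession: str
    count: int


@dataclass
class RccLane:
    """One nCounter lane: code-class-tagged raw counts plus lane metadata.

    ``attributes`` keys coming from a section other than the header are
    namespaced ``Section.Key`` so that e.g. the sample ``ID`` and the lane
    ``ID`` cannot collide; :attr:`lane_id` and :attr:`sample_name` are
    lifted out as first-class fields.
    """

    lane_id: str
    sample_name: str
    records: list[RccRecord]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.code_class not in CODE_CLASSES:
                raise RccFormatError(
                    f"lane {self.lane_id!r}: unknown CodeClass {rec.code_class!r} "
                    f"for gene {rec.gene_name!r}"
                )
            if not isinstance(rec.count, (int, np.integer)) or isinstance(rec.count, bool):
                raise RccFormatError(
                    f"lane {self.lane_id!r}: count for gene {rec.gene_name!r} "
                    f"is not an integer ({rec.count!r})"
                )
            if rec.count < 0:
                raise RccFormatError(
                    f"lane {self.lane_id!r}: negative count for gene {rec.gene_name!r}"
                )
            if rec.gene_name in seen:
                raise RccFormatError(
                    f"lane {self.lane_id!r}: duplicate gene {rec.gene_name!r}"
                )
            seen.add(rec.gene_name)

    def counts(self, code_class: Optional[str] = None) -> dict[str, int]:
        """Gene -> count map, optionally restricted to one code class."""
        return {
            r.gene_name: r.count
            for r in self.records
            if code_class is None or r.code_class == code_class
        }

    @property
    def normalization_eligible(self) -> bool:
        classes = {r.code_class for r in self.records}
        return "Positive" in classes and "Housekeeping" in classes


_SECTION_RE = re.compile(r"^<(?P<name>[A-Za-z_]+)>$")
_SECTION_END_RE = re.compile(r"^</(?P<name>[A-Za-z_]+)>$")


def read_rcc(path: str | Path) -> RccLane:
    """Parse a sectioned RCC lane file into an :class:`RccLane`.

    Raises :class:`RccFormatError` when the ``Code_Summary`` section is
    missing or a count is not a non-negative integer (the offending gene is
    named in the message).
    """
    path = Path(path)
    sections: dict[str, list[str]] = {}
    current: Optional[str] = None
    order: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        m = _SECTION_RE.match(line)
        if m:
            current = m.group("name")
            sections.setdefault(current, [])
            order.append(current)
            continue
        if _SECTION_END_RE.match(line):
            current = None
            continue
        if current is not None:
            sections[current].append(line)

    if "Code_Summary" not in sections:
        raise RccFormatError(f"{path}: missing Code_Summary section")

    attributes: dict[str, str] = {}
    lane_id = ""
    sample_name = ""
    for name in order:
        if name == "Code_Summary":
            continue
        for line in sections[name]:
            key, _, value = line.partition(",")
            if name == "Sample_Attributes" and key == "ID":
                sample_name = value
            elif name == "Lane_Attributes" and key == "ID":
                lane_id = value
            elif name == "Header":
                attributes[key] = value
            else:
                attributes[f"{name}.{key}"] = value

    records: list[RccRecord] = []
    rows = sections["Code_Summary"]
    for line in rows:
        fields = next(csv.reader([line]))
        if [f.strip() for f in fields[:4]] == ["CodeClass", "Name", "Accession", "Count"]:
            continue
        if len(fields) < 4:
            raise RccFormatError(f"{path}: short Code_Summary row {line!r}")
        code_class, gene, accession, count_str = (f.strip() for f in fields[:4])
        try:
            count = int(count_str)
        except ValueError:
            raise RccFormatError(
                f"{path}: non-integer count {count_str!r} for gene {gene!r}"
            ) from None
        records.append(RccRecord(code_class, gene, accession, count))

    return RccLane(lane_id=lane_id, sample_name=sample_name, records=records, attributes=attributes)


def write_rcc(lane: RccLane, path: str | Path) -> None:
    """Write ``lane`` so that :func:`read_rcc` returns an equal object."""
    path = Path(path)
    header_lines: list[str] = []
    sectioned: dict[str, list[str]] = {}
    for key, value in lane.attributes.items():
        section, dot, rest = key.partition(".")
        if dot and section in ("Sample_Attributes", "Lane_Attributes"):
            sectioned.setdefault(section, []).append(f"{rest},{value}")
        else:
            header_lines.append(f"{key},{value}")

    out: list[str] = ["<Header>"]
    out.extend(header_lines)
    out.append("</Header>")
    out.append("<Sample_Attributes>")
    out.append(f"ID,{lane.sample_name}")
    out.extend(sectioned.get("Sample_Attributes", []))
    out.append("</Sample_Attributes>")
    out.append("<Lane_Attributes>")
    out.append(f"ID,{lane.lane_id}")
    out.extend(sectioned.get("Lane_Attributes", []))
    out.append("</Lane_Attributes>")
    out.append("<Code_Summary>")
    out.append("CodeClass,Name,Accession,Count")
    for rec in lane.records:
        out.append(f"{rec.code_class},{rec.gene_name},{rec.accession},{rec.count}")
    out.append("</Code_Summary>")
    path.write_text("\n".join(out) + "\n")


def read_rcc_batch(directory: str | Path, pattern: str = "*.RCC") -> list[RccLane]:
    """Read every RCC file in ``directory`` (case-insensitive extension)."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() == ".rcc"
    )
    if not paths:
        raise FileNotFoundError(f"no .RCC files under {directory}")
    return [read_rcc(p) for p in paths]


def write_rcc_batch(lanes: Sequence[RccLane], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, lane in enumerate(lanes):
        p = directory / f"{i + 1:02d}_{lane.sample_name or lane.lane_id}.RCC"
        write_rcc(lane, p)
        paths.append(p)
    return paths


@dataclass
class ExpressionMatrix:
    """Probes x samples expression values with a scale flag and entity labels.

    ``data`` is a :class:`pandas.DataFrame` indexed by probe id with sample
    ids as columns.  ``scale`` is ``"linear"`` or ``"log2"``.  ``labels``,
    when present, maps *every* sample to an entity string (e.g.
    ``"EPN_RELA"``, ``"ATRT"``); partial label maps are rejected.
    """

    data: pd.DataFrame
    scale: str = "linear"
    labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "log2" and not np.isfinite(values).all():
            raise ValueError("log2 matrix contains non-finite values")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dupes}")
        if self.labels is not None:
            missing = set(self.data.columns) - set(self.labels)
            if missing:
                raise ValueError(f"labels missing for samples: {sorted(missing)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_log2(self) -> "ExpressionMatrix":
        """Return the matrix on the log2 scale (identity if already log2)."""
        if self.scale == "log2":
            return self
        values = self.data.to_numpy(dtype=float)
        if (values <= 0).any():
            raise ValueError("cannot log2-transform non-positive values")
        return ExpressionMatrix(np.log2(self.data), "log2", self.labels)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(probe_ids)], self.scale, self.labels)


def read_expression_matrix(
    path: str | Path, labels_path: Optional[str | Path] = None
) -> ExpressionMatrix:
    """Read a probes x samples TSV (optional ``#scale=`` metadata line)."""
    path = Path(path)
    scale = "linear"
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            m = re.match(r"#\s*scale\s*=\s*(\w+)", line)
            if m:
                scale = m.group(1)
            body_start = i + 1
        else:
            break
    header = lines[body_start].rstrip("\n").split("\t")
    n_cols = len(header)
    sample_ids = header[1:]
    probes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_cols})"
            )
        probes.append(fields[0])
        rows.append([float(x) for x in fields[1:]])
    data = pd.DataFrame(rows, index=probes, columns=sample_ids, dtype=float)

    labels = None
    if labels_path is not None:
        labels = {}
        for lineno, line in enumerate(Path(labels_path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] in ("sample_id", "sample") and lineno == 1:
                continue
            if len(fields) < 2:
                raise ValueError(f"{labels_path}:{lineno}: expected two columns")
            labels[fields[0]] = fields[1]
        unknown = set(labels) - set(sample_ids)
        if unknown:
            raise ValueError(f"label file references unknown samples: {sorted(unknown)}")
    return ExpressionMatrix(data, scale=scale, labels=labels)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            labels_path: Optional[str | Path] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in matrix.data.iterrows():
            fh.write(probe + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    if labels_path is not None and matrix.labels is not None:
        with Path(labels_path).open("w") as fh:
            fh.write("sample_id\tlabel\n")
            for sid in matrix.sample_ids:
                fh.write(f"{sid}\t{matrix.labels[sid]}\n")


@dataclass
class ClinicalRecord:
    """One patient: demographics, molecular group, fusion call and follow-up.

    Follow-up encoding (right censoring):

    * alive disease-free at *m* months  -> ``time_months=m``, ``event_death=False``
    * died of disease at *m* months     -> ``time_months=m``, ``event_death=True``
    * died, month unknown               -> ``time_months=None``, ``event_death=True``
      (kept for counting, excluded from time-to-event analyses)
    * relapse at *r* months             -> ``event_progression=True``,
      ``time_progression_months=r``; otherwise progression is censored at the
      follow-up time.
    """

    patient_id: str
    age_years: float
    sex: str
    group_label: str
    fusion_call: Optional[str]
    time_months: Optional[float]
    event_death: bool
    event_progression: bool
    time_progression_months: Optional[float]
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ClinicalFormatError(
                f"patient {self.patient_id!r}: unknown sex code {self.sex!r}"
            )
        if self.age_years < 0:
            raise ClinicalFormatError(f"patient {self.patient_id!r}: negative age")
        for t in (self.time_months, self.time_progression_months):
            if t is not None and t <= 0:
                raise ClinicalFormatError(
                    f"patient {self.patient_id!r}: non-positive event time {t}"
                )
        if (
            self.time_months is not None
            and self.time_progression_months is not None
            and self.time_progression_months > self.time_months + 1e-9
        ):
            raise ClinicalFormatError(
                f"patient {self.patient_id!r}: progression time exceeds follow-up"
            )


def _clean(value: str) -> Optional[str]:
    value = value.strip()
    if value.lower() in _MISSING:
        return None
    return value


def _find_column(header: Sequence[str], *needles: str) -> Optional[int]:
    for i, col in enumerate(header):
        low = col.lower()
        if any(n in low for n in needles):
            return i
    return None


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV with the published column roles.

    Expected columns (matched loosely, case-insensitive): ID, Age (years),
    Sex, NanoString diagnosis, NGS fusion, Original diagnosis, Relapse
    months, DOD (months), ADF (months).  Rows with both a DOD month and an
    ADF month are rejected — a patient cannot simultaneously be dead and
    alive disease-free.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if any(f.strip() for f in r)]
    if not rows:
        return []
    header = rows[0]
    idx = {
        "id": _find_column(header, "id"),
        "age": _find_column(header, "age"),
        "sex": _find_column(header, "sex"),
        "group": _find_column(header, "nanostring", "group"),
        "fusion": _find_column(header, "fusion"),
        "diagnosis": _find_column(header, "original diagnosis", "who"),
        "relapse": _find_column(header, "relapse"),
        "dod": _find_column(header, "dod"),
        "adf": _find_column(header, "adf"),
    }
    for role in ("id", "age", "sex", "group", "dod", "adf"):
        if idx[role] is None:
            raise ClinicalFormatError(f"{path}: missing column for {role!r}")

    records: list[ClinicalRecord] = []
    for row in rows[1:]:
        def cell(role: str) -> Optional[str]:
            i = idx[role]
            if i is None or i >= len(row):
                return None
            return _clean(row[i])

        pid = cell("id") or ""
        dod = cell("dod")
        adf = cell("adf")
        dod_low = dod.lower() if dod else None
        if dod_low == "no":
            dod = None
            dod_low = None
        dod_months: Optional[float] = None
        died = False
        if dod is not None:
            died = True
            if dod_low != "yes":
                dod_months = float(dod)
        adf_months = float(adf) if adf is not None else None
        if dod_months is not None and adf_months is not None:
            raise ClinicalFormatError(
                f"{path}: patient {pid!r} has both DOD and ADF months set"
            )
        if died:
            time_months = dod_months  # None => death month unknown
        else:
            time_months = adf_months

        relapse = cell("relapse")
        if relapse is not None and relapse.lower() == "no":
            relapse = None
        event_progression = relapse is not None
        if event_progression:
            time_prog: Optional[float] = float(relapse.split("/")[0])
        else:
            time_prog = time_months

        fusion = cell("fusion")
        if fusion is not None and fusion.lower() in ("not detected", "nd"):
            fusion = None

        records.append(
            ClinicalRecord(
                patient_id=pid,
                age_years=float(cell("age") or "nan"),
                sex=cell("sex") or "",
                group_label=cell("group") or "",
                fusion_call=fusion,
                time_months=time_months,
                event_death=died,
                event_progression=event_progression,
                time_progression_months=time_prog,
                diagnosis=cell("diagnosis"),
            )
        )
    return records


_CLINICAL_HEADER = [
    "ID", "Age (years)", "Sex", "NanoString diagnosis", "NGS fusion",
    "Original diagnosis", "Relapse months", "DOD (months)", "ADF (months)",
]


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    """Write records in the published column layout (round-trips with
    :func:`read_clinical_table`)."""
    def fmt(x: Optional[float]) -> str:
        if x is None:
            return "-"
        return f"{x:g}"

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CLINICAL_HEADER)
        for r in records:
            if r.event_death:
                dod = fmt(r.time_months) if r.time_months is not None else "Yes"
                adf = "-"
            else:
                dod = "No"
                adf = fmt(r.time_months)
            relapse = fmt(r.time_progression_months) if r.event_progression else "No"
            writer.writerow([
                r.patient_id, f"{r.age_years:g}", r.sex, r.group_label,
                r.fusion_call if r.fusion_call is not None else "Not detected",
                r.diagnosis if r.diagnosis is not None else "-",
                relapse, dod, adf,
            ])


def load_table2() -> list[ClinicalRecord]:
    """The packaged 15-patient supratentorial clinical table."""
    ref = resources.files("epnsig.data").joinpath("table2_clinical.csv")
    with resources.as_file(ref) as p:
        return read_clinical_table(p)


def write_assignments(assignments, path: str | Path) -> None:
    """Write a group-assignment report TSV (sample_id, label, score, evidence)."""
    with Path(path).open("w") as fh:
        fh.write("sample_id\tlabel\tscore\tevidence\n")
        for a in assignments:
            fh.write(f"{a.sample_id}\t{a.label}\t{a.score:.6g}\t{a.evidence}\n")


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
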