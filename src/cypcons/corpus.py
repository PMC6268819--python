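"""Bundled fixture tables and delimited-text I/O for the classification pipeline.

The training fixture is the 121-drug clinical set (33 potent, 88 weak
inhibitors of CYP3A4, potent = FDA "strong" + "moderate"); the assay fixture
is the 17-drug in-vitro/in-vivo comparison table (HTS IC50 with confidence
interval, maximum recommended daily dose, bioavailability, Cmax).

One curation note: the high-MW half of the published training table loses the
erythromycin row in common text extractions.  It is restored here (MW 734,
potent) so that the printed marginals -- 121 compounds, 33 potent, 82 low-MW,
39 high-MW, 18 potent high-MW -- all hold.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_BAND_THRESHOLD = 450.0

#: average standard error of a multiply-measured HTS IC50, in uM; used as the
#: +/- half-width of the confidence interval when only one measurement exists
SINGLE_MEASUREMENT_CI_HALF_WIDTH = 6.90


class Category(str, Enum):
    POTENT = "P"
    WEAK = "W"
    UNKNOWN = "U"


class Band(str, Enum):
    LOW = "LOW"
    HIGH = "HIGH"


class ValidationError(ValueError):
    """A malformed or physically impossible input row."""


class ReconciliationError(ValueError):
    """Compound identifiers do not match between two input tables."""

    def __init__(self, message: str, missing: Sequence[str] = (), extra: Sequence[str] = ()):
        super().__init__(message)
        self.missing = list(missing)
        self.extra = list(extra)


def band_of(mw: float, band_threshold: float = DEFAULT_BAND_THRESHOLD) -> Band:
    # boundary compounds (mw == threshold) stay in the low band
    return Band.HIGH if mw > band_threshold else Band.LOW


@dataclass(frozen=True)
class CompoundRecord:
    identifier: str
    mw: float
    category: Category
    band: Band

    def __post_init__(self):
        if not self.mw > 0:
            raise ValidationError(f"{self.identifier}: molecular weight must be positive, got {self.mw}")


@dataclass(frozen=True)
class AssayRecord:
    identifier: str
    ic50: float
    ic50_ci: tuple[float, float]
    n_measurements: int
    outcome: str = "ACTIVE"

    def __post_init__(self):
        lo, hi = self.ic50_ci
        if not self.ic50 > 0:
            raise ValidationError(f"{self.identifier}: IC50 must be positive")
        if lo < 0 or not (lo <= self.ic50 <= hi):
            raise ValidationError(f"{self.identifier}: IC50 CI ({lo}, {hi}) must bracket IC50 {self.ic50}")


@dataclass(frozen=True)
class ExposureContext:
    """Exposure quantities needed to turn an IC50 into an AUC fold change.

    mrdd is in mg/kg/day, bioavailability is a fraction in (0, 1], cmax in uM,
    mw in g/mol.  ``ba_adme`` carries the greatest value of a predicted oral
    bioavailability range (used by the R-2 variant); ``route`` records oral vs
    intravenous administration of the MRDD.
    """

    mrdd: float | None = None
    bioavailability: float | None = None
    cmax: float | None = None
    mw: float | None = None
    ba_adme: float | None = None
    route: str = "oral"

    def __post_init__(self):
        for name in ("mrdd", "bioavailability", "cmax", "mw", "ba_adme"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive when present, got {v}")
        for name in ("bioavailability", "ba_adme"):
            v = getattr(self, name)
            if v is not None and v > 1:
                raise ValidationError(f"{name} is a fraction and cannot exceed 1, got {v}")


# --- training fixture: compound, MW (Da), clinical category -----------------

_TRAINING_TABLE = """\
id,mw,category
thiamazole,114,W
isoniazid,137,P
valproic acid,144,W
acetaminophen,151,W
hydralazine,160,W
chlorzoxazone,170,W
metronidazole,171,P
propofol,178,P
selegiline,187,W
dexmedetomidine,200,W
pilocarpine,208,W
methoxsalen,216,W
acetazolamide,222,W
lomustine,234,W
phencyclidine,243,W
cimetidine,252,P
primaquine,259,W
cyclophosphamide,261,W
ifosfamide,261,W
ticlopidine,264,W
mirtazapine,265,W
nevirapine,266,W
orphenadrine,269,W
venlafaxine,277,W
diazepam,285,W
testosterone,288,W
anastrozole,293,W
diclofenac,296,P
cocaine,303,W
entacapone,305,W
fluconazole,306,P
sertraline,306,P
fluoxetine,309,W
methadone,309,W
olanzapine,312,W
pergolide,314,W
efavirenz,316,W
fluvoxamine,318,W
norfloxacin,319,P
chloramphenicol,323,W
quinine,324,W
midazolam,326,W
clozapine,327,W
paroxetine,329,W
ciprofloxacin,331,W
fentanyl,336,W
danazol,337,W
dextropropoxyphene,339,W
methylprednisolone,339,W
clemastine,344,W
clotrimazole,345,P
omeprazole,345,W
nifedipine,346,W
voriconazole,349,P
oxybutynin,357,W
rabeprazole,359,W
nitrendipine,360,W
prednisolone,360,W
drospirenone,367,W
lansoprazole,369,W
tamoxifen,372,W
haloperidol,376,P
mefloquine,378,W
azelastine,382,W
loratadine,383,W
felodipine,384,W
nisoldipine,388,W
betamethasone,392,W
sulconazole,398,W
amlodipine,409,W
risperidone,410,W
fluvastatin,411,W
ziprasidone,413,W
diltiazem,415,P
miconazole,416,P
losartan,423,W
pravastatin,424,W
irbesartan,429,W
mifepristone,430,W
doxycycline,444,P
mitoxantrone,444,W
tetracycline,446,P
verapamil,455,P
delavirdine,457,P
pimozide,462,W
cisapride,466,W
nefazodone,470,P
clofazimine,473,W
sildenafil,475,W
nicardipine,480,P
glibenclamide,494,W
imatinib,494,P
amprenavir,506,P
ketoconazole,531,P
aprepitant,534,P
doxorubicin,544,W
atorvastatin,559,W
nelfinavir,568,P
zafirlukast,576,W
ergotamine,582,W
dihydroergotamine,584,W
etoposide,589,W
indinavir,614,P
amiodarone,645,P
bromocriptine,655,W
teniposide,657,W
saquinavir,671,P
atazanavir,705,P
itraconazole,706,P
ritonavir,721,P
erythromycin,734,P
clarithromycin,748,P
azithromycin,749,W
vinorelbine,779,W
tacrolimus,804,W
docetaxel,808,W
vinblastine,811,W
troleandomycin,814,P
vincristine,825,W
sirolimus,914,W
quinupristin,1022,W
"""

# --- assay fixture: the 17-drug in-vitro -> in-vivo comparison --------------
# columns: id, category, ic50 (uM), ci_lo, ci_hi, n_measurements, mrdd
# (mg/kg/day), route, ba (fraction; empty = not reported), ba_adme (greatest
# value of the predicted range: <30 -> 0.30, 30-70 -> 0.70, >70 -> 1.00),
# cmax (uM; empty = not reported), mw (Da, from the training table)

_EXTRAPOLATION_TABLE = """\
id,category,ic50,ci_lo,ci_hi,n_measurements,mrdd,route,ba,ba_adme,cmax,mw
clotrimazole,P,0.07,0.00,0.17,3,6.67,iv,1.00,0.70,0.087,345
isoniazid,P,9.92,0.00,26.37,2,15,oral,0.80,1.00,76.61,137
diltiazem,P,3.98,0.00,10.88,1,8,oral,0.38,0.30,0.356,415
ketoconazole,P,0.13,0.00,7.03,1,8,oral,0.50,0.70,7,531
glibenclamide,W,5.99,0.00,12.80,3,0.29,oral,0.80,0.70,0.2,494
methoxsalen,W,10.50,3.39,17.61,3,0.6,oral,0.26,1.00,0.184,216
omeprazole,W,10.00,3.10,16.9,1,2,oral,0.47,0.70,,345
clemastine,W,5.01,0.00,13.48,3,0.134,oral,0.37,0.70,0.00233,344
dexmedetomidine,W,0.16,0.00,7.06,1,0.2,iv,1.00,0.70,,200
lansoprazole,W,20.48,7.63,33.33,2,0.5,oral,0.81,0.70,1.92,369
nifedipine,W,11.29,7.70,14.88,2,1.71,oral,0.50,0.70,0.027,346
pilocarpine,W,15.85,8.95,22.75,1,0.5,oral,,0.30,0.099,208
mitoxantrone,W,25.12,18.22,32.02,1,2,iv,1.00,0.30,0.36,444
irbesartan,W,15.85,8.95,22.75,1,5,oral,0.70,0.70,7.98,429
losartan,W,19.95,13.05,26.85,1,1.67,oral,0.36,0.70,0.596,423
sildenafil,W,10.00,3.10,16.9,1,1.67,oral,0.38,0.70,0.447,475
pergolide,W,12.59,5.69,19.49,1,0.05,oral,0.38,0.30,,314
"""


def load_training_fixture(band_threshold: float = DEFAULT_BAND_THRESHOLD) -> list[CompoundRecord]:
    """The 121-drug clinical training set (33 potent, 88 weak)."""
    return _parse_compound_rows(io.StringIO(_TRAINING_TABLE), band_threshold, source="training fixture")


def training_frame(band_threshold: float = DEFAULT_BAND_THRESHOLD) -> pd.DataFrame:
    recs = load_training_fixture(band_threshold)
    return pd.DataFrame(
        {
            "id": [r.identifier for r in recs],
            "mw": [r.mw for r in recs],
            "category": [r.category.value for r in recs],
            "band": [r.band.value for r in recs],
        }
    ).set_index("id")


def load_extrapolation_fixture() -> list[tuple[AssayRecord, ExposureContext, Category]]:
    """The 17-drug IC50/MRDD/bioavailability/Cmax extrapolation table."""
    out = []
    for row in csv.DictReader(io.StringIO(_EXTRAPOLATION_TABLE)):
        assay = AssayRecord(
            identifier=row["id"],
            ic50=float(row["ic50"]),
            ic50_ci=(float(row["ci_lo"]), float(row["ci_hi"])),
            n_measurements=int(row["n_measurements"]),
        )
        ctx = ExposureContext(
            mrdd=float(row["mrdd"]),
            bioavailability=float(row["ba"]) if row["ba"] else None,
            cmax=float(row["cmax"]) if row["cmax"] else None,
            mw=float(row["mw"]),
            ba_adme=float(row["ba_adme"]) if row["ba_adme"] else None,
            route=row["route"],
        )
        out.append((assay, ctx, Category(row["category"])))
    return out


# --- delimited-text readers/writers -----------------------------------------


def _delimiter(dialect: str) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def _parse_compound_rows(handle, band_threshold: float, source: str, delimiter: str = ",") -> list[CompoundRecord]:
    reader = csv.DictReader(handle, delimiter=delimiter)
    required = {"id", "mw"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValidationError(f"{source}: header must contain columns 'id' and 'mw'")
    records = []
    for lineno, row in enumerate(reader, start=2):
        ident = (row.get("id") or "").strip()
        raw_mw = (row.get("mw") or "").strip()
        try:
            mw = float(raw_mw)
        except ValueError:
            raise ValidationError(f"{source}, line {lineno}: molecular weight {raw_mw!r} is not a number") from None
        if not mw > 0 or not math.isfinite(mw):
            raise ValidationError(f"{source}, line {lineno}: molecular weight must be positive, got {mw}")
        if not ident:
            raise ValidationError(f"{source}, line {lineno}: empty compound identifier")
        raw_cat = (row.get("category") or "").strip().upper()
        if raw_cat in ("", "U", "UNKNOWN"):
            cat = Category.UNKNOWN
        elif raw_cat in ("P", "POTENT"):
            cat = Category.POTENT
        elif raw_cat in ("W", "WEAK"):
            cat = Category.WEAK
        else:
            raise ValidationError(f"{source}, line {lineno}: unknown category {raw_cat!r}")
        records.append(CompoundRecord(ident, mw, cat, band_of(mw, band_threshold)))
    return records


def read_compound_table(
    path: str | Path,
    dialect: str = "csv",
    band_threshold: float = DEFAULT_BAND_THRESHOLD,
) -> list[CompoundRecord]:
    """Read a compound table (columns id, mw, optional category)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        return _parse_compound_rows(fh, band_threshold, source=str(path), delimiter=_delimiter(dialect))


def write_compound_table(path: str | Path, records: Iterable[CompoundRecord], dialect: str = "csv") -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(dialect))
        writer.writerow(["id", "mw", "category"])
        for r in records:
            cat = "" if r.category is Category.UNKNOWN else r.category.value
            writer.writerow([r.identifier, repr(r.mw) if r.mw != int(r.mw) else int(r.mw), cat])


def reconcile_identifiers(reference: Sequence[str], other: Sequence[str], what: str) -> None:
    """Raise if the two identifier sets differ, listing the offenders."""
    ref, oth = set(reference), set(other)
    missing = sorted(ref - oth)
    extra = sorted(oth - ref)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing from {what}: {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected in {what}: {', '.join(extra)}")
        raise ReconciliationError("; ".join(parts), missing=missing, extra=extra)


def read_score_matrix(path: str | Path, dialect: str = "csv", compounds: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a compounds x docking-score matrix (first column = compound id)."""
    df = pd.read_csv(path, sep=_delimiter(dialect), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"{path}: missing score values in columns {bad}")
    if compounds is not None:
        reconcile_identifiers(compounds, df.index.tolist(), what=f"score matrix {path}")
        df = df.loc[list(compounds)]
    return df


def read_peak_lists(path: str | Path, dialect: str = "csv", compounds: Sequence[str] | None = None):
    """Read per-compound predicted NMR peaks (columns id, nucleus, shift)."""
    from .sdar import Nucleus, SpectrumPeaks

    shifts: dict[tuple[str, Nucleus], list[float]] = {}
    order: list[tuple[str, Nucleus]] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(dialect))
        if reader.fieldnames is None or not {"id", "nucleus", "shift"}.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: header must contain columns id, nucleus, shift")
        for lineno, row in enumerate(reader, start=2):
            try:
                nucleus = Nucleus.parse(row["nucleus"])
                shift = float(row["shift"])
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from None
            key = (row["id"].strip(), nucleus)
            if key not in shifts:
                shifts[key] = []
                order.append(key)
            shifts[key].append(shift)
    peaks = [SpectrumPeaks(identifier=i, nucleus=n, shifts=tuple(shifts[(i, n)])) for i, n in order]
    if compounds is not None:
        reconcile_identifiers(compounds, [p.identifier for p in peaks], what=f"peak list {path}")
    return peaks


def write_peak_lists(path: str | Path, peaks, dialect: str = "csv") -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(dialect))
        writer.writerow(["id", "nucleus", "shift"])
        for p in peaks:
            for s in p.shifts:
                writer.writerow([p.identifier, p.nucleus.value, repr(float(s))])


def read_descriptor_table(path: str | Path, dialect: str = "csv", compounds: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a compounds x molecular-descriptor table; missing values are an error."""
    df = pd.read_csv(path, sep=_delimiter(dialect), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValidationError(f"{path}: descriptor table has missing values in {bad}; imputation is not supported")
    if compounds is not None:
        reconcile_identifiers(compounds, df.index.tolist(), what=f"descriptor table {path}")
        df = df.loc[list(compounds)]
    return df


def write_matrix(path: str | Path, df: pd.DataFrame, dialect: str = "csv") -> None:
    # repr() of a float is the shortest string that round-trips bit-exactly
    df.to_csv(path, sep=_delimiter(dialect), index_label="id", float_format=lambda x: repr(float(x)))


def write_report(path: str | Path, report: dict) -> None:
    """Serialize an analysis report as structured JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n", encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, Enum):
        return obj.value
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")
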