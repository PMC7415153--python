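"""Shared data model and file I/O for multi-environment trial (MET) data.

A MET couples three tables: environments (location, latitude, planting
date), phenotypes (days-to-heading of a genotype in an environment) and a
biallelic marker matrix coded as allele dosages 0/1/2 with missing values.
Files are plain CSV (UTF-8, header row) with ISO-8601 dates; markers may
alternatively come from a VCF of biallelic SNPs.

Days to heading (DTH) is the day-count difference heading date minus
seeding date.  Day 1 of any day-length series is the planting date itself,
so the conventions here and in :mod:`daycast.daylength` agree.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Environment", "PhenotypeRecord", "MarkerMatrix", "MetDataset",
    "read_phenotypes", "read_markers", "write_markers",
    "write_predictions", "read_predictions",
]


@dataclass(frozen=True)
class Environment:
    """One trial environment: a location x planting-date combination."""

    env_id: str
    latitude: float
    planting_date: dt.date
    longitude: float = math.nan  # informational; unused by the day-length model
    label: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"environment {self.env_id}: latitude {self.latitude} "
                "outside [-90, 90]")
        if not isinstance(self.planting_date, dt.date):
            raise ValidationError(
                f"environment {self.env_id}: planting_date must be a date")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Observed days-to-heading of one genotype in one environment."""

    genotype_id: str
    env_id: str
    dth: int

    def __post_init__(self) -> None:
        if int(self.dth) != self.dth or self.dth < 1:
            raise ValidationError(
                f"({self.genotype_id}, {self.env_id}): dth must be a "
                f"positive integer, got {self.dth!r}")


@dataclass
class MarkerMatrix:
    """Genotype x marker allele-dosage table.

    ``calls`` is a float array with entries in {0, 1, 2} or NaN for
    missing.  Heterozygous VCF calls are mapped to missing on read, the
    treatment appropriate for highly inbred (self-pollinating) material.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n_g, n_m = len(self.genotype_ids), len(self.marker_ids)
        if self.calls.shape != (n_g, n_m):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_g} genotypes x {n_m} markers")
        if len(set(self.genotype_ids)) != n_g:
            raise ValidationError("duplicate genotype ids in marker matrix")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.calls[~valid].flat[0]
            raise FormatError(
                f"marker dosage {bad!r} outside {{0, 1, 2, missing}}")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_genotypes(self, keep: Sequence[str]) -> "MarkerMatrix":
        index = {g: i for i, g in enumerate(self.genotype_ids)}
        missing = [g for g in keep if g not in index]
        if missing:
            raise ValidationError(f"unknown genotype ids: {missing[:5]}")
        rows = [index[g] for g in keep]
        return MarkerMatrix(list(keep), list(self.marker_ids),
                            self.calls[rows, :].copy())


@dataclass
class MetDataset:
    """Joined phenotype + environment (+ optional marker) data for a MET."""

    environments: list[Environment]
    phenotypes: list[PhenotypeRecord]
    markers: MarkerMatrix | None = None

    def __post_init__(self) -> None:
        env_ids = [e.env_id for e in self.environments]
        if len(set(env_ids)) != len(env_ids):
            raise ValidationError("duplicate environment ids")
        self._env_by_id = {e.env_id: e for e in self.environments}
        seen: set[tuple[str, str]] = set()
        for rec in self.phenotypes:
            if rec.env_id not in self._env_by_id:
                raise ValidationError(
                    f"phenotype references unknown environment {rec.env_id}")
            key = (rec.genotype_id, rec.env_id)
            if key in seen:
                raise ValidationError(f"duplicate phenotype record {key}")
            seen.add(key)
        if self.markers is not None:
            known = set(self.markers.genotype_ids)
            orphans = {r.genotype_id for r in self.phenotypes} - known
            if orphans:
                raise ValidationError(
                    f"phenotyped genotypes absent from marker matrix: "
                    f"{sorted(orphans)[:5]}")

    # -- lookups ---------------------------------------------------------
    @property
    def env_ids(self) -> list[str]:
        return [e.env_id for e in self.environments]

    @property
    def genotype_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.phenotypes:
            seen.setdefault(rec.genotype_id, None)
        return list(seen)

    def environment(self, env_id: str) -> Environment:
        try:
            return self._env_by_id[env_id]
        except KeyError:
            raise ValidationError(f"unknown environment {env_id}") from None

    def records_for_genotype(self, genotype_id: str) -> list[PhenotypeRecord]:
        return [r for r in self.phenotypes if r.genotype_id == genotype_id]

    def records_for_env(self, env_id: str) -> list[PhenotypeRecord]:
        return [r for r in self.phenotypes if r.env_id == env_id]

    def observed_dth(self, genotype_id: str, env_id: str) -> int | None:
        for r in self.phenotypes:
            if r.genotype_id == genotype_id and r.env_id == env_id:
                return r.dth
        return None

    def exclude(self, *, env_id: str | None = None,
                genotype_id: str | None = None) -> "MetDataset":
        """Copy of the dataset with all records of an environment and/or a
        genotype removed (environments themselves are kept so day-length
        series remain available)."""
        kept = [r for r in self.phenotypes
                if (env_id is None or r.env_id != env_id)
                and (genotype_id is None or r.genotype_id != genotype_id)]
        return MetDataset(self.environments, kept, self.markers)

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.genotype_id, r.env_id, r.dth) for r in self.phenotypes],
            columns=["genotype_id", "env_id", "dth"])


# ---------------------------------------------------------------------------
# phenotype / environment tables

_CANONICAL = ("genotype_id", "env_id", "latitude", "longitude",
              "planting_date", "heading_date", "dth", "label")


def _parse_date(text: str, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(text).strip())
    except ValueError:
        raise FormatError(
            f"row {row}: cannot parse {column} {text!r} as ISO date") from None


def read_phenotypes(path: str | Path,
                    dialect: Mapping[str, str] | None = None,
                    ) -> tuple[list[Environment], list[PhenotypeRecord]]:
    """Read a phenotype CSV into environments and phenotype records.

    The file must carry per-row environment metadata (env_id, latitude,
    planting_date) plus genotype_id and either ``dth`` directly or a
    ``heading_date`` from which DTH is computed as the whole-day difference
    heading - planting.  `dialect` maps canonical column names to the
    actual header names in the file.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, dtype=str)
    col = {c: dialect.get(c, c) for c in _CANONICAL}
    for required in ("genotype_id", "env_id", "latitude", "planting_date"):
        if col[required] not in df.columns:
            raise FormatError(f"missing required column {col[required]!r}")
    has_dth = col["dth"] in df.columns
    has_heading = col["heading_date"] in df.columns
    if not (has_dth or has_heading):
        raise FormatError(
            f"need either column {col['dth']!r} or {col['heading_date']!r}")

    env_seen: dict[str, Environment] = {}
    records: list[PhenotypeRecord] = []
    keys: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        env_id = str(row[col["env_id"]]).strip()
        genotype_id = str(row[col["genotype_id"]]).strip()
        planting = _parse_date(row[col["planting_date"]], i, "planting_date")
        try:
            latitude = float(row[col["latitude"]])
        except (TypeError, ValueError):
            raise FormatError(
                f"row {i}: latitude {row[col['latitude']]!r} not numeric"
            ) from None
        longitude = math.nan
        if col["longitude"] in df.columns and pd.notna(row[col["longitude"]]):
            longitude = float(row[col["longitude"]])
        label = ""
        if col["label"] in df.columns and pd.notna(row[col["label"]]):
            label = str(row[col["label"]])
        env = Environment(env_id, latitude, planting, longitude, label)
        prior = env_seen.setdefault(env_id, env)
        if (prior.latitude, prior.planting_date) != (latitude, planting):
            raise FormatError(
                f"row {i}: environment {env_id} redefined with different "
                "latitude/planting date")

        if has_dth and pd.notna(row[col["dth"]]):
            try:
                dth = int(str(row[col["dth"]]).strip())
            except ValueError:
                raise FormatError(
                    f"row {i}: dth {row[col['dth']]!r} not an integer"
                ) from None
            if has_heading and pd.notna(row.get(col["heading_date"])):
                heading = _parse_date(row[col["heading_date"]], i,
                                      "heading_date")
                if (heading - planting).days != dth:
                    raise FormatError(
                        f"row {i}: dth {dth} inconsistent with "
                        f"heading - planting = {(heading - planting).days}")
        else:
            heading = _parse_date(row[col["heading_date"]], i, "heading_date")
            dth = (heading - planting).days
        key = (genotype_id, env_id)
        if key in keys:
            raise ValidationError(f"row {i}: duplicate record {key}")
        keys.add(key)
        records.append(PhenotypeRecord(genotype_id, env_id, dth))
    return list(env_seen.values()), records


# ---------------------------------------------------------------------------
# marker matrices

def read_markers(path: str | Path, format: str = "matrix_csv") -> MarkerMatrix:
    """Read a marker matrix from a dosage CSV or a biallelic-SNP VCF.

    matrix_csv: genotypes as rows (first column = genotype id), markers as
    columns, cells in {0, 1, 2, NA}.

    vcf: parsed with cyvcf2; heterozygous calls become missing (inbred-line
    assumption), ``./.`` is missing, multiallelic sites are skipped with a
    logged count, marker ids are CHROM:POS.
    """
    if format == "matrix_csv":
        df = pd.read_csv(path, index_col=0)
        if df.empty:
            raise FormatError(f"{path}: empty marker matrix")
        calls = df.to_numpy(dtype=float)
        return MarkerMatrix([str(g) for g in df.index],
                            [str(m) for m in df.columns], calls)
    if format == "vcf":
        return _read_vcf(path)
    raise FormatError(f"unknown marker format {format!r}")


def _read_vcf(path: str | Path) -> MarkerMatrix:
    from cyvcf2 import VCF  # deferred: only VCF users need the binding

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dosage = np.full(gt.shape, np.nan)
        dosage[gt == 0] = 0.0
        dosage[gt == 3] = 2.0  # het (1) and unknown (2) stay missing
        marker_ids.append(f"{variant.CHROM}:{variant.POS}")
        columns.append(dosage)
    vcf.close()
    if not columns:
        raise FormatError(f"{path}: no biallelic SNPs found")
    if n_multiallelic:
        logger.info("skipped %d multiallelic sites in %s",
                    n_multiallelic, path)
    return MarkerMatrix(samples, marker_ids, np.column_stack(columns))


def write_markers(markers: MarkerMatrix, path: str | Path) -> None:
    """Write a dosage matrix CSV (missing as NA) readable by read_markers."""
    df = pd.DataFrame(markers.calls, index=markers.genotype_ids,
                      columns=markers.marker_ids)
    # integral dosages print as integers, missing as empty (pandas NA)
    df = df.astype("Int64")
    df.to_csv(path)


# ---------------------------------------------------------------------------
# prediction tables

_PRED_COLUMNS = ["genotype_id", "env_id", "scheme", "method",
                 "predicted_dth", "observed_dth"]


def write_predictions(results: Iterable, path: str | Path) -> None:
    """Write prediction results as CSV, ordered by environment then
    genotype; predicted DTH with two decimals, observed blank if unknown."""
    rows = []
    for r in results:
        rows.append((r.genotype_id, r.env_id, r.scheme, r.method,
                     f"{r.predicted_dth:.2f}",
                     "" if r.observed_dth is None else str(int(r.observed_dth))))
    if not rows:
        raise ValidationError("no prediction results to write")
    rows.sort(key=lambda t: (t[1], t[0]))
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV back into a DataFrame (observed_dth nullable)."""
    df = pd.read_csv(path, dtype={"genotype_id": str, "env_id": str})
    missing = [c for c in _PRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"predictions file lacks columns {missing}")
    df["observed_dth"] = df["observed_dth"].astype("Float64")
    return df
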