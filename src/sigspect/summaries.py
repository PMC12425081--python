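"""Cohort summaries and bit-stable CSV/JSON table export.

Every table the pipeline draws (spectra, exposures, trees, boxplot
summaries) can be exported as CSV (RFC 4180 quoting, '.' decimal
separator, LF line endings) or JSON (UTF-8, insertion-ordered keys).
Floats are written with round-trip-safe ``repr`` so re-reading reproduces
every value exactly, and identical inputs always produce byte-identical
files (no timestamps, no unordered-map iteration).

The mutation-count boxplot summary uses log base 10 and "type 7" linear
interpolation of order statistics for the quartiles.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .channels import SBS96_LABELS
from .cluster import ClusterNode, tree_from_dict, tree_to_dict
from .fitting import CohortExposures, ExposureResult, relative_exposures
from .spectra import SpectrumMatrix


@dataclass(frozen=True)
class GroupSummary:
    """Five-number summary of log10 mutation totals for one group."""

    group: str
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def log_count_summary(
    spectra: SpectrumMatrix, groups: Mapping[str, str]
) -> list[GroupSummary]:
    """Per-group five-number summaries of log10(total mutations).

    Every sample must be assigned a group. Zero-mutation samples are
    excluded with a warning before taking logs; a group left empty after
    exclusions is omitted with a warning. Groups are reported in
    first-appearance order over the spectrum's samples.
    """
    missing = [s for s in spectra.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing[:5]}")
    by_group: dict[str, list[float]] = {}
    dropped = 0
    totals = spectra.counts.sum(axis=1)
    for sample_id, total in zip(spectra.sample_ids, totals):
        if total < 1:
            dropped += 1
            by_group.setdefault(groups[sample_id], [])
            continue
        by_group.setdefault(groups[sample_id], []).append(math.log10(total))
    if dropped:
        warnings.warn(
            f"excluded {dropped} zero-mutation sample(s) before log transform",
            stacklevel=2,
        )
    summaries = []
    for group, values in by_group.items():
        if not values:
            warnings.warn(f"group {group!r} empty after exclusions; omitted",
                          stacklevel=2)
            continue
        arr = np.asarray(values)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        summaries.append(
            GroupSummary(
                group=group,
                n=len(values),
                minimum=float(arr.min()),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                maximum=float(arr.max()),
            )
        )
    return summaries


def _fmt(value) -> str:
    """Round-trip-safe cell formatting: ints plain, floats via repr."""
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def export_csv(
    rows: Sequence[Sequence], header: Sequence[str], path: str | Path
) -> None:
    """Generic RFC 4180 CSV export with LF endings and repr floats."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(list(header))
        for row in rows:
            writer.writerow([_fmt(v) for v in row])


def export_json(obj, path: str | Path) -> None:
    """Deterministic JSON export (UTF-8, stable insertion key order)."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(obj, handle, indent=2, ensure_ascii=False)
        handle.write("\n")


def write_spectrum_csv(spectra: SpectrumMatrix, path: str | Path) -> None:
    """COSMIC-style layout: header ``MutationType,<sample...>`` then 96
    channel rows in canonical order."""
    header = ["MutationType"] + list(spectra.sample_ids)
    rows = [
        [label] + [int(c) for c in spectra.counts[:, i]]
        for i, label in enumerate(SBS96_LABELS)
    ]
    export_csv(rows, header, path)


def read_spectrum_csv(path: str | Path) -> SpectrumMatrix:
    """Inverse of :func:`write_spectrum_csv` (exclusion tallies are not
    stored in the CSV and come back as zero)."""
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        if not header or header[0] != "MutationType":
            raise ValueError(f"{path}: not a spectrum CSV (no MutationType column)")
        sample_ids = header[1:]
        counts = np.zeros((len(sample_ids), 96), dtype=np.int64)
        seen = 0
        for row in reader:
            if not row:
                continue
            label = row[0]
            if label not in SBS96_LABELS:
                raise ValueError(f"{path}: unknown channel label {label!r}")
            idx = SBS96_LABELS.index(label)
            counts[:, idx] = [int(v) for v in row[1:]]
            seen += 1
        if seen != 96:
            raise ValueError(f"{path}: expected 96 channel rows, found {seen}")
    return SpectrumMatrix(
        sample_ids=sample_ids,
        counts=counts,
        excluded=np.zeros(len(sample_ids), dtype=np.int64),
        excluded_by_reason=[{} for _ in sample_ids],
    )


def write_exposures_csv(cohort: CohortExposures, path: str | Path) -> None:
    """Exposure matrix CSV: ``Sample,<sig1>,...,<sigK>,r_norm``."""
    header = ["Sample"] + list(cohort.signature_ids) + ["r_norm"]
    rows = [
        [sample_id]
        + [float(e) for e in cohort.exposures[i]]
        + [float(cohort.r_norm[i])]
        for i, sample_id in enumerate(cohort.sample_ids)
    ]
    export_csv(rows, header, path)


def read_exposures_csv(path: str | Path) -> CohortExposures:
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        if len(header) < 3 or header[0] != "Sample" or header[-1] != "r_norm":
            raise ValueError(f"{path}: not an exposure CSV")
        signature_ids = header[1:-1]
        sample_ids: list[str] = []
        exposures: list[list[float]] = []
        r_norm: list[float] = []
        for row in reader:
            if not row:
                continue
            sample_ids.append(row[0])
            exposures.append([float(v) for v in row[1:-1]])
            r_norm.append(float(row[-1]))
    return CohortExposures(
        sample_ids=sample_ids,
        signature_ids=signature_ids,
        exposures=np.asarray(exposures).reshape(len(sample_ids), len(signature_ids)),
        r_norm=np.asarray(r_norm),
    )


def relative_exposure_record(result: ExposureResult) -> dict:
    """JSON-ready per-sample record {sample, exposures: {sig: prop}, r_norm}."""
    rel = relative_exposures(result)
    return {
        "sample": result.sample_id,
        "exposures": {
            sig: float(p) for sig, p in zip(result.signature_ids, rel)
        },
        "r_norm": result.r_norm,
    }


def write_tree_json(tree: ClusterNode, path: str | Path) -> None:
    export_json(tree_to_dict(tree), path)


def read_tree_json(path: str | Path) -> ClusterNode:
    with open(path, "r", encoding="utf-8") as handle:
        return tree_from_dict(json.load(handle))


def write_summary_csv(summaries: Sequence[GroupSummary], path: str | Path) -> None:
    """Boxplot-summary CSV; the header names the log10 scale explicitly."""
    header = [
        "group", "n",
        "min_log10", "q1_log10", "median_log10", "q3_log10", "max_log10",
    ]
    rows = [
        [s.group, s.n, s.minimum, s.q1, s.median, s.q3, s.maximum]
        for s in summaries
    ]
    export_csv(rows, header, path)


def write_heatmap_csv(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    row_order: Sequence[str],
    col_order: Sequence[str],
    path: str | Path,
) -> None:
    """Exposure heatmap with rows and columns in clustered order."""
    matrix = np.asarray(matrix, dtype=float)
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: i for i, c in enumerate(col_ids)}
    header = ["Sample"] + list(col_order)
    rows = [
        [r] + [float(matrix[ri[r], ci[c]]) for c in col_order] for r in row_order
    ]
    export_csv(rows, header, path)
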