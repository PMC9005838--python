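"""Reading prediction tables and writing validation reports.

A prediction table is a delimited text file (CSV/TSV) with a header row and
one row per subject: a predicted-risk column (values in [0, 1]) and a
binary outcome column.  Reports bundle the unified calibration test, the
comparator tests, the discrimination summaries and full provenance (seed,
replicate count, package version, input checksum) as JSON, with ROC/mROC
curve vertices exportable as TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from ._version import __version__
from .calibration import CalibrationTestResult
from .curves import StepCurve
from .sample import PredictionSample

__all__ = ["read_prediction_table", "write_report", "file_sha256"]

logger = logging.getLogger(__name__)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_prediction_table(
    path,
    risk_column: str = "risk",
    outcome_column: str = "outcome",
    delimiter: str | None = None,
) -> PredictionSample:
    """Parse and validate a delimited prediction table.

    The delimiter defaults to tab for ``.tsv`` files and comma otherwise.
    Validation errors cite the offending (1-based) data row.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in (risk_column, outcome_column):
        if col not in df.columns:
            raise ValueError(
                f"{path}: column {col!r} not found; available columns: "
                f"{', '.join(map(str, df.columns))}"
            )

    def _numeric(col: str) -> pd.Series:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValueError(
                f"{path}: non-numeric or missing {col!r} value "
                f"{df[col].iloc[bad[0]]!r} at data row {row}"
            )
        return vals

    risks = _numeric(risk_column)
    outcomes = _numeric(outcome_column)
    out_of_range = risks.index[(risks < 0) | (risks > 1)]
    if len(out_of_range):
        row = int(out_of_range[0]) + 1
        raise ValueError(
            f"{path}: risk {risks.iloc[out_of_range[0]]!r} outside [0, 1] "
            f"at data row {row}"
        )
    not_binary = outcomes.index[~outcomes.isin((0, 1))]
    if len(not_binary):
        row = int(not_binary[0]) + 1
        raise ValueError(
            f"{path}: outcome {df[outcome_column].iloc[not_binary[0]]!r} is not "
            f"0 or 1 at data row {row}"
        )
    sample = PredictionSample(risks.to_numpy(dtype=float), outcomes.to_numpy(dtype=float))
    logger.info(
        "read %d rows from %s: %d events (prevalence %.3f), mean risk %.3f",
        sample.n, path, sample.n_events, sample.prevalence, sample.mean_risk,
    )
    return sample


def write_report(
    result: CalibrationTestResult,
    reference_results: dict | None = None,
    curves: dict[str, StepCurve] | None = None,
    path=None,
    fmt: str = "json",
    input_checksum: str | None = None,
    reproducible: bool = False,
) -> dict:
    """Assemble (and optionally write) the full validation report.

    ``curves`` maps names (e.g. ``"roc"``, ``"mroc"``) to
    :class:`StepCurve`; with ``fmt="tsv"`` each curve is written next to
    the JSON report as ``<stem>.<name>.tsv``, and areas under the curves
    are embedded in the report either way.  ``reproducible=True`` omits the
    timestamp so that repeated runs with a pinned seed are byte-identical.
    """
    if fmt not in ("json", "tsv"):
        raise ValueError(f"unknown report format {fmt!r}; use 'json' or 'tsv'")
    report: dict = {
        "schema": "mroc-report/1",
        "version": __version__,
        "calibration_test": result.to_dict(),
    }
    if not reproducible:
        report["created"] = datetime.now(timezone.utc).isoformat()
    if input_checksum is not None:
        report["input_sha256"] = input_checksum
    if reference_results:
        report["reference_tests"] = reference_results
    if curves:
        report["auc"] = {name: curve.auc for name, curve in curves.items()}
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if fmt == "tsv" and curves:
            for name, curve in curves.items():
                curve.to_tsv(path.with_suffix(f".{name}.tsv"))
        logger.info("wrote report to %s", path)
    return report
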