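"""CSV/JSON round-tripping for the pipeline file formats.

Conventions: comma-separated UTF-8 with a mandatory header row, '.'
decimal, ISO-8601 dates, units embedded in column names.  Run metadata
(seed, config hash, package version, timestamp) is isolated in leading
``#`` comment lines so that data rows are byte-reproducible for a given
seed.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .assess import DosePrediction, PatientGeometry, SourceImplant
from .transport import DepthDoseSeries, TallyResult

PATIENT_COLUMNS = [
    "patient_id",
    "sk_U",
    "lambda_cGy_h_U",
    "cf",
    "implant_date",
    "wet_ant_cm",
    "wet_post_cm",
    "wet_left_cm",
    "wet_right_cm",
]

PREDICTION_COLUMNS = ["patient_id", "direction", "distance_cm", "h10_uSv_h", "eval_date"]

SERIES_COLUMNS = [
    "distance_cm",
    "depth_cm",
    "h10_per_decay_pSv",
    "rel_se",
    "n_histories",
    "seed",
]


class SchemaError(ValueError):
    """An input file does not match the expected column schema."""


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _metadata_comment(seed: int | None, config: Mapping | None) -> str:
    parts = [f"version={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    parts.append(f"written={_dt.datetime.now().isoformat(timespec='seconds')}")
    return "# " + " ".join(parts) + "\n"


def _write_csv(df: pd.DataFrame, path: Path, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_comment(seed, config))
        df.to_csv(fh, index=False)


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# depth-dose series


def write_series(
    series_list: Sequence[DepthDoseSeries], path: str | Path, seed=None, config=None
) -> None:
    records = [r for s in series_list for r in s.to_records()]
    _write_csv(pd.DataFrame.from_records(records, columns=SERIES_COLUMNS), Path(path), seed, config)


def read_series(path: str | Path) -> list[DepthDoseSeries]:
    df = _read_csv(Path(path), SERIES_COLUMNS)
    out = []
    for distance, grp in df.groupby("distance_cm", sort=True):
        grp = grp.sort_values("depth_cm")
        points = tuple(
            (
                float(row.depth_cm),
                TallyResult(
                    h10_per_decay_pSv=float(row.h10_per_decay_pSv),
                    rel_se=float(row.rel_se),
                    n_histories=int(row.n_histories),
                    seed=int(row.seed),
                ),
            )
            for row in grp.itertuples()
        )
        out.append(DepthDoseSeries(distance_cm=float(distance), points=points))
    return out


# ---------------------------------------------------------------------------
# patients and predictions


def write_patients(
    cohort: Sequence[tuple[PatientGeometry, SourceImplant]],
    path: str | Path,
    seed=None,
    config=None,
) -> None:
    rows = []
    for pid, (geometry, implant) in enumerate(cohort):
        rows.append(
            {
                "patient_id": pid,
                "sk_U": implant.sk_U,
                "lambda_cGy_h_U": implant.dose_rate_constant_cGy_h_U,
                "cf": implant.cf_Sv_Gy,
                "implant_date": implant.implant_date.isoformat()
                if implant.implant_date
                else "",
                "wet_ant_cm": geometry.anterior_cm,
                "wet_post_cm": geometry.posterior_cm,
                "wet_left_cm": geometry.left_cm,
                "wet_right_cm": geometry.right_cm,
            }
        )
    _write_csv(pd.DataFrame.from_records(rows, columns=PATIENT_COLUMNS), Path(path), seed, config)


def read_patients(path: str | Path) -> list[tuple[PatientGeometry, SourceImplant]]:
    df = _read_csv(Path(path), PATIENT_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples()):
        try:
            geometry = PatientGeometry(
                anterior_cm=float(row.wet_ant_cm),
                posterior_cm=float(row.wet_post_cm),
                left_cm=float(row.wet_left_cm),
                right_cm=float(row.wet_right_cm),
            )
            implant_date = (
                _dt.date.fromisoformat(str(row.implant_date))
                if isinstance(row.implant_date, str) and row.implant_date
                else None
            )
            implant = SourceImplant(
                sk_U=float(row.sk_U),
                dose_rate_constant_cGy_h_U=float(row.lambda_cGy_h_U),
                cf_Sv_Gy=float(row.cf),
                implant_date=implant_date,
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad value in row {i}: {exc}") from exc
        out.append((geometry, implant))
    return out


def write_predictions(
    predictions: Mapping[int, Sequence[DosePrediction]],
    path: str | Path,
    seed=None,
    config=None,
) -> None:
    rows = [
        {
            "patient_id": pid,
            "direction": p.direction,
            "distance_cm": p.distance_cm,
            "h10_uSv_h": p.h10_uSv_h,
            "eval_date": p.eval_date.isoformat() if p.eval_date else "",
        }
        for pid, preds in predictions.items()
        for p in preds
    ]
    _write_csv(
        pd.DataFrame.from_records(rows, columns=PREDICTION_COLUMNS), Path(path), seed, config
    )


def read_predictions(path: str | Path) -> pd.DataFrame:
    return _read_csv(Path(path), PREDICTION_COLUMNS)
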