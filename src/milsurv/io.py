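"""On-disk formats: HDF5 feature bags and CSV cohort/curve/score tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data import HORIZON, ClinicalCovariates, Cohort, FeatureBag, SurvivalRecord

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_curves",
    "read_curves",
    "write_scores",
    "read_scores",
]

_CURVE_COLS = [f"S_{k}" for k in range(1, HORIZON + 1)]


def write_cohort(cohort: Cohort, outdir) -> tuple[Path, Path]:
    """Write ``features.h5`` (group /patients/<id>/features, float32) and
    ``cohort.csv`` into ``outdir``; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h5_path = outdir / "features.h5"
    with h5py.File(h5_path, "w") as f:
        patients = f.create_group("patients")
        for bag in cohort.bags:
            patients.create_group(bag.patient_id).create_dataset(
                "features", data=bag.features.astype(np.float32)
            )
    csv_path = outdir / "cohort.csv"
    cohort.frame().to_csv(csv_path, index=False)
    return h5_path, csv_path


def read_cohort(features_h5, cohort_csv, name: str | None = None) -> Cohort:
    """Load a cohort written by :func:`write_cohort` (latent truth is not
    on disk and comes back as ``None``)."""
    table = pd.read_csv(cohort_csv, keep_default_na=False)
    bags, records, covs = [], [], []
    with h5py.File(features_h5, "r") as f:
        for _, row in table.iterrows():
            pid = str(row["patient_id"])
            bags.append(FeatureBag(pid, f["patients"][pid]["features"][()]))
            records.append(
                SurvivalRecord(float(row["time_months"]), bool(int(row["event"])))
            )
            covs.append(
                ClinicalCovariates(
                    age_group=row["age_group"], T=row["T"], N=row["N"],
                    M=row["M"], UICC=row["UICC"] or None,
                )
            )
    cohort_name = name or (str(table["cohort"].iloc[0]) if len(table) else "cohort")
    return Cohort(bags, records, covs, latent_risk=None, name=cohort_name)


def write_curves(patient_ids, curves: np.ndarray, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(curves), columns=_CURVE_COLS)
    df.insert(0, "patient_id", list(patient_ids))
    df.to_csv(path, index=False)
    return path


def read_curves(path) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path)
    return df["patient_id"].tolist(), df[_CURVE_COLS].to_numpy(dtype=float)


def write_scores(patient_ids, scores: np.ndarray, path,
                 column: str = "mortality_score") -> Path:
    path = Path(path)
    pd.DataFrame({"patient_id": list(patient_ids), column: np.asarray(scores)}).to_csv(
        path, index=False
    )
    return path


def read_scores(path, column: str = "mortality_score") -> tuple[list, np.ndarray]:
    df = pd.read_csv(path)
    return df["patient_id"].tolist(), df[column].to_numpy(dtype=float)
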