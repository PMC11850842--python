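"""Readers and writers for the plain-text formats the pipeline touches.

Conventions: methylation and annotation are TSV; prescriptions are CSV
with either ISO dates or integer day offsets; GRMs are dense square TSV or
lower-triangle ``id1 id2 value`` triplets; annotation positions are
1-based inclusive and converted to 0-based half-open only in the BED
writer.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import PrescriptionRecord
from .mps import MpsModel
from .mwas import MethylationMatrix, RelatednessMatrix, beta_to_m

__all__ = [
    "read_methylation",
    "write_methylation",
    "read_annotation",
    "write_annotation",
    "read_phenotypes",
    "write_phenotypes",
    "read_prescriptions",
    "write_prescriptions",
    "read_grm",
    "write_grm",
    "read_results",
    "write_results",
    "write_dmr_bed",
    "read_mps_model",
    "write_mps_model",
]

EPOCH = date(1970, 1, 1)


def read_methylation(
    path, scale: str = "M", to_m: bool = False, max_missing: float = 0.05
) -> MethylationMatrix:
    """Read a probe x sample TSV (probe_id index, sample-id header).

    Probes with more than ``max_missing`` missing values are dropped; the
    rest are mean-imputed.  ``to_m`` converts beta input to M-values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id in {path}: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id in {path}: {dup}")
    frac_missing = df.isna().mean(axis=1)
    df = df[frac_missing <= max_missing]
    if df.isna().any().any():
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    values = df.to_numpy(dtype=float)
    if scale == "beta" and to_m:
        values = beta_to_m(values)
        scale = "M"
    return MethylationMatrix(
        values, df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object), scale=scale
    )


def write_methylation(mat: MethylationMatrix, path) -> None:
    # %.17g round-trips float64 exactly through text
    mat.to_frame().to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    if ann["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    if (ann["position"] <= 0).any():
        raise ValueError("annotation positions must be positive (1-based)")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype table")
    return df.set_index("sample_id")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample_id")


def _parse_day(value) -> int:
    """ISO date or integer offset -> integer days from the 1970 epoch."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    s = str(value)
    try:
        return int(s)
    except ValueError:
        return (datetime.strptime(s, "%Y-%m-%d").date() - EPOCH).days


def read_prescriptions(path) -> list:
    df = pd.read_csv(path, dtype={"person_id": str, "drug_code": str})
    records = []
    for row in df.itertuples(index=False):
        quantity = None if pd.isna(row.quantity) else float(row.quantity)
        dose = None if pd.isna(row.daily_dose) else float(row.daily_dose)
        records.append(
            PrescriptionRecord(
                str(row.person_id), _parse_day(row.dispense_day), str(row.drug_code),
                quantity, dose,
            )
        )
    return records


def write_prescriptions(records, path) -> None:
    pd.DataFrame(
        {
            "person_id": [r.person_id for r in records],
            "dispense_day": [r.dispense_day for r in records],
            "drug_code": [r.drug_code for r in records],
            "quantity": [r.quantity for r in records],
            "daily_dose": [r.daily_dose for r in records],
        }
    ).to_csv(path, index=False)


def read_grm(path, kind: str = "GRM") -> RelatednessMatrix:
    """Dense square TSV (sample-id header + index) or 3-column triplets."""
    probe = pd.read_csv(path, sep="\t", nrows=1)
    if probe.shape[1] == 3 and set(probe.columns) >= {"id1", "id2", "value"}:
        trip = pd.read_csv(path, sep="\t")
        ids = pd.unique(pd.concat([trip["id1"], trip["id2"]]).astype(str))
        pos = {s: i for i, s in enumerate(ids)}
        K = np.zeros((len(ids), len(ids)))
        for row in trip.itertuples(index=False):
            i, j = pos[str(row.id1)], pos[str(row.id2)]
            K[i, j] = K[j, i] = float(row.value)
        return RelatednessMatrix(K, np.array(ids, dtype=object), kind=kind)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelatednessMatrix(
        df.to_numpy(dtype=float), df.columns.to_numpy(dtype=object), kind=kind
    )


def write_grm(K: RelatednessMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.sample_ids, columns=K.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


RESULT_COLUMNS = ["probe_id", "chromosome", "position", "gene", "beta", "se", "p", "n", "analysis"]


def write_results(results: pd.DataFrame, annotation: pd.DataFrame, path) -> None:
    """Summary-statistics TSV with the shared column order."""
    ann = annotation.set_index("probe_id")
    out = results.copy()
    out["chromosome"] = [ann.at[p, "chromosome"] for p in out["probe_id"]]
    out["position"] = [ann.at[p, "position"] for p in out["probe_id"]]
    out["gene"] = [ann.at[p, "gene"] for p in out["probe_id"]]
    out[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dmr_bed(dmr_frame: pd.DataFrame, path) -> None:
    """BED-compatible DMR output: 0-based half-open coordinates."""
    bed = pd.DataFrame(
        {
            "chrom": dmr_frame["chromosome"],
            "start": dmr_frame["start_bp"] - 1,
            "end": dmr_frame["end_bp"],
            "n_probes": dmr_frame["n_probes"],
            "beta": dmr_frame["beta"],
            "se": dmr_frame["se"],
            "p": dmr_frame["p"],
            "p_adj": dmr_frame["p_adj"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_mps_model(model: MpsModel, path) -> None:
    """TSV of probe_id/weight plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "probe_id": list(model.weights),
            "weight": [model.weights[p] for p in model.weights],
            "train_mean": [model.train_mean[p] for p in model.weights],
            "train_sd": [model.train_sd[p] for p in model.weights],
        }
    ).to_csv(path, sep="\t", index=False)
    meta = {
        "mask_description": model.mask_description,
        "cv_folds": model.cv_folds,
        "seed": model.seed,
        "penalty": model.penalty,
        "intercept": model.intercept,
        "penalty_rule": "cv-min",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_mps_model(path) -> MpsModel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return MpsModel(
        weights=dict(zip(df["probe_id"], df["weight"])),
        train_mean=dict(zip(df["probe_id"], df["train_mean"])),
        train_sd=dict(zip(df["probe_id"], df["train_sd"])),
        mask_description=meta["mask_description"],
        cv_folds=meta["cv_folds"],
        seed=meta["seed"],
        penalty=meta["penalty"],
        intercept=meta["intercept"],
    )
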