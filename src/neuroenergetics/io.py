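"""Standard-format I/O: TSV regional tables, JSON patterns, CSV curves, NIfTI.

TSV dialect: tab-separated, UTF-8, header row of region names, first column
``subject_id``.  Curves are two-column CSV (``time_min,value``).  Patterns
and result files are JSON.  Parametric and label volumes go through NIfTI
via nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .quantification import LabelVolume, PlasmaInputCurve, TimeActivityCurve
from .ssm_pca import CovariancePattern
from .synthetic_cohort import DiseasePattern, RegionalDataset
from .energetics import EnergeticsTable

__all__ = [
    "write_regional_dataset", "read_regional_dataset",
    "write_energetics_table", "read_energetics_table",
    "write_pattern", "read_pattern",
    "write_disease_pattern", "read_disease_pattern",
    "write_curve", "read_curve",
    "write_volume", "read_volume", "read_label_volume",
]


# %.17g guarantees bit-exact float64 round trips through text
_FLOAT_FMT = "%.17g"


def _write_matrix(path: Path, matrix: np.ndarray, subject_ids, region_names):
    df = pd.DataFrame(matrix, columns=list(region_names))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_matrix(path: Path):
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "subject_id":
        raise ValueError(f"{path}: first column must be 'subject_id'")
    regions = header[1:]
    if len(set(regions)) != len(regions):
        raise ValueError(f"{path}: duplicate region columns")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return (df["subject_id"].astype(str).tolist(), regions,
            df.iloc[:, 1:].to_numpy(dtype=float))


def write_regional_dataset(ds: RegionalDataset, out_dir) -> Path:
    """One TSV per modality plus subject- and region-metadata TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_matrix(out / "cmrglu.tsv", ds.cmrglu, ds.subject_ids, ds.region_names)
    _write_matrix(out / "cbf.tsv", ds.cbf, ds.subject_ids, ds.region_names)
    pd.DataFrame({"subject_id": ds.subject_ids, "age": ds.ages,
                  "sex": ds.sex}).to_csv(out / "subjects.tsv", sep="\t",
                                         index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"region": ds.region_names,
                  "group": [ds.region_groups.get(r, "other")
                            for r in ds.region_names]}
                 ).to_csv(out / "regions.tsv", sep="\t", index=False)
    return out


def read_regional_dataset(in_dir) -> RegionalDataset:
    src = Path(in_dir)
    ids_g, regions_g, cmrglu = _read_matrix(src / "cmrglu.tsv")
    ids_f, regions_f, cbf = _read_matrix(src / "cbf.tsv")
    if ids_g != ids_f or regions_g != regions_f:
        raise ValueError("cmrglu.tsv and cbf.tsv disagree on subjects/regions")
    meta = pd.read_csv(src / "subjects.tsv", sep="\t",
                       float_precision="round_trip")
    meta = meta.set_index(meta["subject_id"].astype(str)).loc[ids_g]
    rmeta = pd.read_csv(src / "regions.tsv", sep="\t")
    groups = dict(zip(rmeta["region"], rmeta["group"]))
    return RegionalDataset(cmrglu=cmrglu, cbf=cbf,
                           ages=meta["age"].to_numpy(float),
                           sex=meta["sex"].to_numpy(int),
                           region_names=regions_g, region_groups=groups,
                           subject_ids=ids_g)


def write_energetics_table(table: EnergeticsTable, out_dir,
                           sidecar: dict | None = None) -> Path:
    """Four TSV matrices plus a JSON sidecar (provenance, parameters)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("z_cmrglu", "z_cbf", "rep", "rag"):
        _write_matrix(out / f"{name}.tsv", table.metric(name),
                      table.subject_ids, table.region_names)
    (out / "energetics.json").write_text(
        json.dumps(sidecar or {}, indent=2, sort_keys=True))
    return out


def read_energetics_table(in_dir) -> EnergeticsTable:
    src = Path(in_dir)
    mats = {}
    ids = regions = None
    for name in ("z_cmrglu", "z_cbf", "rep", "rag"):
        ids_n, regions_n, mats[name] = _read_matrix(src / f"{name}.tsv")
        if ids is None:
            ids, regions = ids_n, regions_n
        elif (ids_n, regions_n) != (ids, regions):
            raise ValueError("energetics matrices disagree on subjects/regions")
    return EnergeticsTable(subject_ids=ids, region_names=regions, **mats)


def write_pattern(pattern: CovariancePattern, path) -> Path:
    path = Path(path)
    payload = {
        "metric": pattern.metric,
        "region_names": pattern.region_names,
        "weights": pattern.weights.tolist(),
        "weight_sd": pattern.weight_sd.tolist(),
        "scores": pattern.scores.tolist(),
        "subject_ids": pattern.subject_ids,
        "stats": {
            "separation_t": pattern.separation_t,
            "separation_p": pattern.separation_p,
            "cohens_d": pattern.cohens_d,
            "age_r2": pattern.age_r2,
            "age_p": pattern.age_p,
        },
        "components_used": {str(k): v
                            for k, v in pattern.components_used.items()},
        "n_folds_retained": pattern.n_folds_retained,
        "n_folds_total": pattern.n_folds_total,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_pattern(path) -> CovariancePattern:
    d = json.loads(Path(path).read_text())
    return CovariancePattern(
        metric=d["metric"], region_names=d["region_names"],
        weights=np.asarray(d["weights"], float),
        weight_sd=np.asarray(d["weight_sd"], float),
        scores=np.asarray(d["scores"], float),
        subject_ids=d["subject_ids"],
        separation_t=d["stats"]["separation_t"],
        separation_p=d["stats"]["separation_p"],
        cohens_d=d["stats"]["cohens_d"],
        age_r2=d["stats"]["age_r2"], age_p=d["stats"]["age_p"],
        components_used={int(k): v
                         for k, v in d.get("components_used", {}).items()},
        n_folds_retained=d.get("n_folds_retained", 0),
        n_folds_total=d.get("n_folds_total", 0))


def write_disease_pattern(dp: DiseasePattern, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "label": dp.label,
        "region_names": dp.region_names,
        "weights": dp.rdrp.tolist(),
        "gmp": dp.rgmp.tolist(),
    }, indent=2))
    return path


def read_disease_pattern(path) -> DiseasePattern:
    d = json.loads(Path(path).read_text())
    return DiseasePattern(region_names=d["region_names"],
                          rdrp=np.asarray(d["weights"], float),
                          rgmp=np.asarray(d["gmp"], float),
                          label=d.get("label", ""))


def write_curve(curve, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_min": curve.times,
                  "value": curve.values}).to_csv(path, index=False,
                                                 float_format=_FLOAT_FMT)
    return path


def read_curve(path, kind: str = "tissue"):
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_min", "value"]:
        raise ValueError(f"{path}: expected 'time_min,value' header")
    cls = TimeActivityCurve if kind == "tissue" else PlasmaInputCurve
    return cls(df["time_min"].to_numpy(float), df["value"].to_numpy(float))


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data), affine
                             if affine is not None else np.eye(4)), path)
    return path


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj)


def read_label_volume(path, names: dict[int, str], ap_axis: int = 1,
                      anterior_low: bool = True) -> LabelVolume:
    """Load an integer NIfTI label volume; AP-axis metadata is explicit."""
    data = np.asarray(nib.load(path).dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    return LabelVolume(data=data.astype(np.int32), names=names,
                       ap_axis=ap_axis, anterior_low=anterior_low)
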