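"""NIfTI / CSV / JSON serialisation of pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from lesionrad.synthetic import Subject, VolumePair
from lesionrad.tables import FeatureTable


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume_pair(pair: VolumePair, directory, compress: bool = True) -> None:
    """Write ``<id>_T2 / _MPR / _mask`` NIfTI-1 volumes (mask as uint8)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    aff = _affine(pair.spacing)
    nib.save(nib.Nifti1Image(pair.t2.astype(np.float32), aff),
             directory / f"{pair.subject.id}_T2{ext}")
    nib.save(nib.Nifti1Image(pair.mpr.astype(np.float32), aff),
             directory / f"{pair.subject.id}_MPR{ext}")
    nib.save(nib.Nifti1Image(pair.mask.astype(np.uint8), aff),
             directory / f"{pair.subject.id}_mask{ext}")


def write_volume_cohort(pairs, directory, compress: bool = True) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        write_volume_pair(pair, directory, compress)
        s = pair.subject
        rows.append({"subject_id": s.id, "diagnosis": s.diagnosis, "scanner": s.scanner,
                     "age": s.age, "sex": s.sex, "edss": s.edss, "duration": s.duration})
    pd.DataFrame(rows).to_csv(directory / "subjects.csv", index=False)


def read_volume_cohort(directory) -> list[VolumePair]:
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    pairs = []
    for _, row in subjects.iterrows():
        sid = row["subject_id"]
        imgs = {}
        for tag in ("T2", "MPR", "mask"):
            for ext in (".nii.gz", ".nii"):
                path = directory / f"{sid}_{tag}{ext}"
                if path.exists():
                    imgs[tag] = nib.load(path)
                    break
            else:
                raise FileNotFoundError(f"missing {tag} volume for subject {sid}")
        spacing = tuple(float(v) for v in imgs["T2"].header.get_zooms()[:3])
        subj = Subject(id=sid, diagnosis=row["diagnosis"], scanner=row["scanner"],
                       age=float(row["age"]), sex=int(row["sex"]),
                       edss=float(row["edss"]), duration=float(row["duration"]))
        pairs.append(VolumePair(
            t2=np.asarray(imgs["T2"].dataobj, dtype=float),
            mpr=np.asarray(imgs["MPR"].dataobj, dtype=float),
            mask=np.asarray(imgs["mask"].dataobj) > 0,
            spacing=spacing, subject=subj))
    return pairs


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def feature_table_round_trip(table: FeatureTable, path) -> FeatureTable:
    table.to_csv(path)
    return FeatureTable.from_csv(path)
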