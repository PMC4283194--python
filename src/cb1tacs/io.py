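"""CSV readers/writers for cohorts, TACs and input functions.

File layout of a cohort directory (comma-separated, header row, UTF-8,
times in seconds, activities in kBq/ml):

* ``schedule.csv`` - frame_start_s, frame_duration_s, injection_offset_s
* ``cohort.csv``   - subject_id, session, age_y, weight_kg, dose_MBq, interval_d
* ``tacs.csv``     - subject_id, session, region_id, frame_index,
  value_kBq_ml, trues_rate
* ``input.csv``    - subject_id, session, time_s, parent_plasma, whole_blood
* optionally ``ground_truth.csv`` when the cohort is synthetic

Writers prepend ``#``-prefixed provenance comment lines (version, seed,
config hash) which the readers skip.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import FrameSchedule, InputFunction, SubjectSession, TimeActivityCurve

__all__ = [
    "load_reference_cohort", "read_cohort", "write_cohort",
    "write_region_table", "read_table", "save_map_nifti", "load_map_nifti",
]


def load_reference_cohort() -> pd.DataFrame:
    """Demographics/injectate table of the 15-subject reference study
    cohort (two sessions per subject) that the synthetic generator and the
    validation targets emulate."""
    with importlib.resources.files("cb1tacs.data").joinpath(
            "reference_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def _to_csv(df: pd.DataFrame, path: Path, provenance: Optional[dict]):
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    """Read a package CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#")


def write_region_table(table: pd.DataFrame, path,
                       provenance: Optional[dict] = None) -> None:
    """Write a region-level result table with optional provenance header."""
    _to_csv(table.reset_index() if table.index.name else table,
            Path(path), provenance)


def write_cohort(sessions: List[SubjectSession], directory,
                 truth_frame: Optional[pd.DataFrame] = None,
                 provenance: Optional[dict] = None) -> None:
    """Write a cohort to the documented CSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sched = sessions[0].schedule
    _to_csv(pd.DataFrame({
        "frame_start_s": sched.frame_start,
        "frame_duration_s": sched.frame_duration,
        "injection_offset_s": np.full(sched.n_frames, sched.injection_offset),
    }), directory / "schedule.csv", provenance)

    demo_rows, tac_rows, input_rows = [], [], []
    for s in sessions:
        demo_rows.append(dict(subject_id=s.subject_id, session=s.session,
                              age_y=s.age, weight_kg=s.weight,
                              dose_MBq=s.injected_dose,
                              interval_d=s.scan_interval))
        for region, tac in s.tacs.items():
            for i, v in enumerate(tac.values):
                tac_rows.append(dict(
                    subject_id=s.subject_id, session=s.session,
                    region_id=region, frame_index=i, value_kBq_ml=v,
                    trues_rate=(np.nan if tac.trues_rate is None
                                else tac.trues_rate[i])))
        if s.input is not None:
            input_rows.append(pd.DataFrame({
                "subject_id": s.subject_id, "session": s.session,
                "time_s": s.input.time,
                "parent_plasma": s.input.parent_plasma,
                "whole_blood": s.input.whole_blood,
            }))
    _to_csv(pd.DataFrame(demo_rows), directory / "cohort.csv", provenance)
    _to_csv(pd.DataFrame(tac_rows), directory / "tacs.csv", provenance)
    if input_rows:
        _to_csv(pd.concat(input_rows, ignore_index=True),
                directory / "input.csv", provenance)
    if truth_frame is not None:
        _to_csv(truth_frame, directory / "ground_truth.csv", provenance)


def _require_columns(df: pd.DataFrame, cols, name: str):
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{name} lacks mandatory columns: {sorted(missing)}")


def read_cohort(directory, require_input: bool = True) -> List[SubjectSession]:
    """Read a cohort directory written by :func:`write_cohort`.

    Validates the schedule, frame counts and session completeness; a
    subject with a missing session raises an error naming both.
    """
    directory = Path(directory)
    sched_df = read_table(directory / "schedule.csv")
    _require_columns(sched_df, ["frame_start_s", "frame_duration_s"],
                     "schedule.csv")
    offset = (float(sched_df["injection_offset_s"].iloc[0])
              if "injection_offset_s" in sched_df else 0.0)
    schedule = FrameSchedule(sched_df["frame_start_s"].to_numpy(),
                             sched_df["frame_duration_s"].to_numpy(),
                             injection_offset=offset)

    demo = read_table(directory / "cohort.csv")
    _require_columns(demo, ["subject_id", "session", "age_y", "weight_kg",
                            "dose_MBq", "interval_d"], "cohort.csv")
    tacs = read_table(directory / "tacs.csv")
    _require_columns(tacs, ["subject_id", "session", "region_id",
                            "frame_index", "value_kBq_ml"], "tacs.csv")
    inputs: Dict[tuple, InputFunction] = {}
    input_path = directory / "input.csv"
    if input_path.exists():
        inp_df = read_table(input_path)
        _require_columns(inp_df, ["subject_id", "session", "time_s",
                                  "parent_plasma", "whole_blood"], "input.csv")
        for (sid, sess), grp in inp_df.groupby(["subject_id", "session"]):
            grp = grp.sort_values("time_s")
            inputs[(sid, sess)] = InputFunction(
                time=grp["time_s"].to_numpy(),
                parent_plasma=grp["parent_plasma"].to_numpy(),
                whole_blood=grp["whole_blood"].to_numpy())
    elif require_input:
        raise ValueError("input.csv is missing and require_input=True")

    sessions = []
    for sid, subj_demo in demo.groupby("subject_id", sort=False):
        have = set(subj_demo["session"])
        for needed in ("test", "retest"):
            if needed not in have:
                raise ValueError(
                    f"subject {sid!r} is missing its {needed!r} session")
        for _, row in subj_demo.iterrows():
            key = (sid, row["session"])
            sub_tacs = {}
            sel = tacs[(tacs.subject_id == sid) & (tacs.session == row["session"])]
            for region, grp in sel.groupby("region_id", sort=False):
                grp = grp.sort_values("frame_index")
                if len(grp) != schedule.n_frames:
                    raise ValueError(
                        f"TAC {sid}/{row['session']}/{region} has "
                        f"{len(grp)} frames, schedule has {schedule.n_frames}")
                trues = grp["trues_rate"].to_numpy() if "trues_rate" in grp else None
                if trues is not None and np.all(np.isnan(trues)):
                    trues = None
                sub_tacs[region] = TimeActivityCurve(
                    region_id=region,
                    values=grp["value_kBq_ml"].to_numpy(),
                    schedule=schedule, trues_rate=trues)
            sessions.append(SubjectSession(
                subject_id=str(sid), session=str(row["session"]),
                age=float(row["age_y"]), weight=float(row["weight_kg"]),
                injected_dose=float(row["dose_MBq"]),
                scan_interval=float(row["interval_d"]),
                tacs=sub_tacs, input=inputs.get(key)))
    return sessions


def save_map_nifti(data: np.ndarray, path, voxel_size_mm=(2.0, 2.0, 2.0)):
    """Write a 3-D/4-D volume as NIfTI (requires nibabel)."""
    import nibabel as nib
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def load_map_nifti(path) -> np.ndarray:
    """Read a NIfTI volume back as a float array (requires nibabel)."""
    import nibabel as nib
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
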