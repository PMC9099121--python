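"""NONMEM-convention dataset reading/writing and validation.

The PK table uses the usual columns: ID, TIME (h), AMT (mg, dose rows),
DV (ng/mL, observation rows), EVID (0 observation / 1 dose), MDV, BLQ,
CMT plus covariate columns.  Dose rows carry AMT > 0 and an empty DV;
observation rows carry an empty AMT.  Times must be nonnegative and
nondecreasing within subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import ConcObservation, DoseEvent, SubjectRecord

PK_REQUIRED = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "BLQ", "CMT"]


class DatasetError(ValueError):
    """Schema or row-level validation failure."""


@dataclass
class AnalysisDataset:
    """Validated trio of PK, outcome and AE tables."""

    pk: pd.DataFrame
    outcomes: pd.DataFrame = field(default_factory=pd.DataFrame)
    ae: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        validate_pk_table(self.pk)

    def to_subjects(self) -> list:
        """Materialise SubjectRecord objects from the tables."""
        cov_cols = [c for c in self.pk.columns if c not in PK_REQUIRED]
        out = []
        outcome_by_id = {}
        if len(self.outcomes):
            outcome_by_id = self.outcomes.set_index("subject").to_dict("index")
        for sid, grp in self.pk.groupby("ID", sort=True):
            doses = [
                DoseEvent(time=float(r.TIME), amount=float(r.AMT))
                for r in grp[grp.EVID == 1].itertuples()
            ]
            obs = [
                ConcObservation(
                    time=float(r.TIME),
                    value=float(r.DV) if np.isfinite(r.DV) else 0.0,
                    blq=bool(r.BLQ),
                )
                for r in grp[grp.EVID == 0].itertuples()
            ]
            cov = {c: grp.iloc[0][c] for c in cov_cols}
            cov = {k.lower(): v for k, v in cov.items()}
            out.append(
                SubjectRecord(
                    subject_id=int(sid), covariates=cov, doses=doses,
                    observations=obs,
                    outcomes=dict(outcome_by_id.get(sid, {})),
                )
            )
        return out


def validate_pk_table(pk: pd.DataFrame) -> None:
    missing = [c for c in PK_REQUIRED if c not in pk.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    problems = []
    bad_evid = pk.index[~pk.EVID.isin([0, 1])]
    if len(bad_evid):
        problems.append(f"EVID not in {{0,1}} at rows {list(bad_evid[:5])}")
    neg = pk.index[pk.TIME < 0]
    if len(neg):
        subj = sorted(pk.loc[neg, "ID"].unique().tolist())
        problems.append(f"negative TIME for subjects {subj} (rows {list(neg[:5])})")
    doses = pk[pk.EVID == 1]
    if len(doses) and not (doses.AMT > 0).all():
        bad = doses.index[~(doses.AMT > 0)]
        problems.append(f"dose rows with AMT <= 0 at rows {list(bad[:5])}")
    if len(doses) and doses.DV.notna().any():
        bad = doses.index[doses.DV.notna()]
        problems.append(f"dose rows with DV present at rows {list(bad[:5])}")
    obs = pk[pk.EVID == 0]
    if len(obs) and obs.AMT.notna().any():
        bad = obs.index[obs.AMT.notna()]
        problems.append(f"observation rows with AMT present at rows {list(bad[:5])}")
    non_monotone = []
    for sid, grp in pk.groupby("ID"):
        if np.any(np.diff(grp.TIME.to_numpy()) < 0):
            non_monotone.append(sid)
    if non_monotone:
        problems.append(f"non-monotone TIME within subjects {sorted(non_monotone)}")
    if problems:
        raise DatasetError("; ".join(problems))


def subjects_to_pk_table(subjects) -> pd.DataFrame:
    """NONMEM-style PK table (doses and observations interleaved by time,
    dose first on ties so same-time samples read as pre-dose)."""
    rows = []
    for s in subjects:
        cov = {k.upper(): v for k, v in s.covariates.items()}
        for d in s.doses:
            rows.append({"ID": s.subject_id, "TIME": d.time, "AMT": d.amount,
                         "DV": np.nan, "EVID": 1, "MDV": 1, "BLQ": 0,
                         "CMT": 1, **cov})
        for o in s.observations:
            rows.append({"ID": s.subject_id, "TIME": o.time, "AMT": np.nan,
                         "DV": o.value, "EVID": 0, "MDV": 0,
                         "BLQ": int(o.blq), "CMT": 2, **cov})
    df = pd.DataFrame(rows)
    return df.sort_values(["ID", "TIME", "EVID"],
                          ascending=[True, True, False]).reset_index(drop=True)


def write_dataset(ds: AnalysisDataset, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"pk": outdir / "pk.csv"}
    ds.pk.to_csv(paths["pk"], index=False)
    if len(ds.outcomes):
        paths["outcomes"] = outdir / "outcomes.csv"
        ds.outcomes.to_csv(paths["outcomes"], index=False)
    if len(ds.ae):
        paths["ae"] = outdir / "ae.csv"
        ds.ae.to_csv(paths["ae"], index=False)
    return paths


def read_dataset(path) -> AnalysisDataset:
    """Read a dataset directory (pk.csv required, outcomes.csv / ae.csv
    optional) or a single PK CSV file."""
    path = Path(path)
    if path.is_dir():
        pk_path = path / "pk.csv"
        out_path = path / "outcomes.csv"
        ae_path = path / "ae.csv"
    else:
        pk_path, out_path, ae_path = path, None, None
    if not pk_path.exists():
        raise DatasetError(f"PK table not found at {pk_path}")
    pk = pd.read_csv(pk_path)
    outcomes = (pd.read_csv(out_path) if out_path and out_path.exists()
                else pd.DataFrame())
    ae = pd.read_csv(ae_path) if ae_path and ae_path.exists() else pd.DataFrame()
    return AnalysisDataset(pk=pk, outcomes=outcomes, ae=ae)


def trial_to_dataset(trial) -> AnalysisDataset:
    """Flatten a simulated trial into the analysis tables."""
    pk = subjects_to_pk_table(trial.subjects)
    outcomes = trial.tte.merge(trial.responses, on="subject")
    outcomes = outcomes.rename(columns={"time": "pfs_day", "event": "pfs_event"})
    outcomes = outcomes.merge(
        trial.dose_reduction.rename(
            columns={"time": "reduction_time", "reduced": "reduced"}),
        on="subject",
    )
    eot = {s.subject_id: s.outcomes["end_of_treatment_day"] for s in trial.subjects}
    outcomes["end_of_treatment_day"] = outcomes["subject"].map(eot)
    ae = pd.DataFrame(
        [{"subject": r.subject, "term": r.ae_term, "grade": r.grade,
          "onset_day": r.onset_day} for r in trial.ae_records]
    )
    return AnalysisDataset(pk=pk, outcomes=outcomes, ae=ae)
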