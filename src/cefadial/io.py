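"""File formats: NONMEM-style event CSVs, session/covariate tables, configs.

Event CSV columns: ID, TIME (h), EVID (0 observation / 1 dose), AMT (mg),
RATE (mg/h) or DURATION (h), DV (mg/L), MDV.  Sessions CSV: ID, START, END,
DMSA (optional).  Covariates CSV: ID, BW, HT (cm), SEX, ALB, DMSA
(optional).  Comma-separated, '.' decimal, header row mandatory; times are
hours from each subject's first event.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import SubjectCovariates
from .dataset import DEFAULT_LOQ, ObservationDataset, SubjectData
from .pk import DialysisSession, EventSchedule, InfusionEvent


class ParseError(ValueError):
    pass


def _require(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_dataset(event_csv, sessions_csv=None, covariates_csv=None,
                 loq: float = DEFAULT_LOQ) -> ObservationDataset:
    """Read and validate a multi-subject dataset from CSV files."""
    ev = pd.read_csv(event_csv)
    _require(ev, ["ID", "TIME", "EVID"], str(event_csv))
    has_rate = "RATE" in ev.columns
    has_dur = "DURATION" in ev.columns
    if not has_rate and not has_dur:
        raise ParseError(f"{event_csv}: need a RATE or DURATION column for doses")

    sess = pd.DataFrame(columns=["ID", "START", "END", "DMSA"])
    if sessions_csv is not None:
        sess = pd.read_csv(sessions_csv)
        _require(sess, ["ID", "START", "END"], str(sessions_csv))
    covs = pd.DataFrame(columns=["ID", "BW"])
    if covariates_csv is not None:
        covs = pd.read_csv(covariates_csv)
        _require(covs, ["ID", "BW"], str(covariates_csv))
    covs = covs.set_index("ID")

    subjects = []
    for sid, g in ev.groupby("ID", sort=False):
        g = g.reset_index()
        if np.any(np.diff(g["TIME"].to_numpy()) < 0):
            bad = int(np.where(np.diff(g["TIME"].to_numpy()) < 0)[0][0]) + 1
            raise ParseError(f"{event_csv}: subject {sid}: times not sorted at "
                             f"row index {g['index'][bad]}")
        infusions, times, dv, blq = [], [], [], []
        for _, row in g.iterrows():
            if int(row["EVID"]) == 1:
                amt = float(row.get("AMT", np.nan))
                if not np.isfinite(amt) or amt <= 0:
                    raise ParseError(f"{event_csv}: row {int(row['index'])}: dose "
                                     f"with AMT {row.get('AMT')!r}")
                if has_rate and np.isfinite(row.get("RATE", np.nan)) \
                        and row["RATE"] > 0:
                    dur = amt / float(row["RATE"])
                elif has_dur and np.isfinite(row.get("DURATION", np.nan)) \
                        and row["DURATION"] > 0:
                    dur = float(row["DURATION"])
                else:
                    raise ParseError(f"{event_csv}: row {int(row['index'])}: dose "
                                     "without RATE and without DURATION")
                infusions.append(InfusionEvent(float(row["TIME"]), dur, amt))
            else:
                val = float(row.get("DV", np.nan))
                mdv = int(row.get("MDV", 0)) if np.isfinite(row.get("MDV", 0)) else 0
                if mdv == 1:
                    continue
                if not np.isfinite(val):
                    raise ParseError(f"{event_csv}: row {int(row['index'])}: "
                                     "observation without DV")
                times.append(float(row["TIME"]))
                dv.append(val)
                blq.append(val < loq)
        ssub = sess[sess["ID"] == sid]
        dsessions = [DialysisSession(float(r["START"]), float(r["END"]),
                                     dmsa=float(r["DMSA"])
                                     if "DMSA" in ssub.columns
                                     and np.isfinite(r.get("DMSA", np.nan))
                                     else None)
                     for _, r in ssub.iterrows()]
        horizon = max([t for t in times] + [ev_.end for ev_ in infusions]
                      + [s.end for s in dsessions] + [0.0])
        schedule = EventSchedule(infusions, dsessions, horizon)
        if sid in covs.index:
            c = covs.loc[sid]
            sc = SubjectCovariates(
                bw=float(c["BW"]),
                ht=float(c["HT"]) / 100.0 if "HT" in covs.columns
                and np.isfinite(c.get("HT", np.nan)) else None,
                sex=("female" if str(c.get("SEX", "M")).upper().startswith("F")
                     or str(c.get("SEX", "0")) == "1" else "male"),
                albumin=float(c["ALB"]) if "ALB" in covs.columns
                and np.isfinite(c.get("ALB", np.nan)) else None,
                dmsa=float(c["DMSA"]) if "DMSA" in covs.columns
                and np.isfinite(c.get("DMSA", np.nan)) else None)
        else:
            raise ParseError(f"{covariates_csv}: no covariates for subject {sid}")
        subjects.append(SubjectData(str(sid), schedule, sc,
                                    np.asarray(times), np.asarray(dv),
                                    np.asarray(blq)))
    return ObservationDataset(subjects, loq)


def write_dataset(dataset: ObservationDataset, event_csv, sessions_csv,
                  covariates_csv) -> None:
    """Write a dataset back to the three CSV files (round-trips read_dataset)."""
    ev_rows, sess_rows, cov_rows = [], [], []
    for s in dataset.subjects:
        for ev in s.schedule.infusions:
            ev_rows.append({"ID": s.subject_id, "TIME": ev.start, "EVID": 1,
                            "AMT": ev.amount, "RATE": ev.rate, "DV": np.nan,
                            "MDV": 1})
        for t, y in zip(s.obs_times, s.obs_conc):
            ev_rows.append({"ID": s.subject_id, "TIME": t, "EVID": 0,
                            "AMT": np.nan, "RATE": np.nan, "DV": y, "MDV": 0})
        for sess in s.schedule.sessions:
            sess_rows.append({"ID": s.subject_id, "START": sess.start,
                              "END": sess.end, "DMSA": sess.dmsa})
        c = s.covariates
        cov_rows.append({"ID": s.subject_id, "BW": c.bw,
                         "HT": c.ht * 100.0 if c.ht else np.nan,
                         "SEX": "F" if c.sex == "female" else "M",
                         "ALB": c.albumin, "DMSA": c.dmsa})
    pd.DataFrame(ev_rows).sort_values(["ID", "TIME", "EVID"]).to_csv(
        event_csv, index=False)
    pd.DataFrame(sess_rows).to_csv(sessions_csv, index=False)
    pd.DataFrame(cov_rows).to_csv(covariates_csv, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "model", "estimation", "simulation", "dosing", "seed", "output_dir",
    "verbosity",
}


def load_config(path) -> dict:
    """YAML (or JSON) run configuration; unknown top-level keys rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg


def model_from_config(block: dict):
    """Build a PopulationModel from a config 'model' block."""
    from .covariates import CovariateEffect
    from .model import PopulationModel, ResidualErrorModel, final_published_model

    if not block or block.get("published", False):
        return final_published_model()
    error = ResidualErrorModel(block.get("error", {}).get("kind", "proportional"),
                               a=block.get("error", {}).get("a", 0.0),
                               b=block.get("error", {}).get("b", 0.398))
    effects = [CovariateEffect(**e) for e in block.get("covariate_effects", [])]
    return PopulationModel(typicals=dict(block.get("typicals")),
                           omega=dict(block.get("omega")),
                           error=error, covariate_effects=effects,
                           structure=block.get("structure", "1cmt"))


def write_provenance(outdir, command: str, params: dict) -> None:
    """Machine-readable record sufficient to re-run a command."""
    import platform
    import sys
    import time

    from . import __version__

    rec = {"command": command, "parameters": params,
           "package_version": __version__,
           "python": sys.version.split()[0],
           "platform": platform.platform(),
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    Path(outdir, "provenance.json").write_text(json.dumps(rec, indent=2,
                                                          default=str))
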