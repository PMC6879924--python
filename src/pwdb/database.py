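"""Database generation: simulate virtual-subject grids and manage results.

A database run simulates the baseline subject of every requested age first,
then the offset-grid subjects, extracts the pulse wave indexes for each,
applies the blood-pressure plausibility filter, and writes:

* an HDF5 container with ``/subjects/<label>/sites/<site>/{P,U,A,Q,PPG}``
  and per-subject metadata, and
* a CSV index/manifest (one row per subject: age, the six offsets, derived
  parameters, indexes, convergence and plausibility flags) that serves as
  the database index and can be consumed without any binary reader.

Runs are resumable: subjects whose results already exist in the container
under an identical configuration hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .aging import (SubjectConfig, generate_grid, load_plausibility_reference,
                    plausibility_filter)
from .analysis import index_report
from .errors import PwdbError
from .pipeline import simulate_virtual_subject
from .solver import SolverOptions

__all__ = ["RunManifest", "run_database", "case3_records", "load_index"]

log = logging.getLogger("pwdb")


def _config_hash(subject: SubjectConfig, options: SolverOptions) -> str:
    payload = json.dumps({"age": subject.age, "offsets": subject.offsets,
                          "values": subject.values,
                          "options": vars(options), "version": __version__},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-run bookkeeping: one entry per simulated subject."""

    version: str = __version__
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _store_subject(h5: h5py.File, label: str, pws, subject: SubjectConfig,
                   cfg_hash: str) -> None:
    grp = h5.require_group(f"subjects/{label}")
    grp.attrs["age"] = subject.age
    grp.attrs["config_hash"] = cfg_hash
    grp.attrs["converged"] = pws.converged
    grp.attrs["n_cycles"] = pws.n_cycles_run
    grp.attrs["offsets"] = json.dumps(subject.offsets)
    grp.attrs["values"] = json.dumps(subject.values)
    for site, kinds in pws.waves.items():
        sg = grp.require_group(f"sites/{site}")
        for kind, wave in kinds.items():
            if kind in sg:
                del sg[kind]
            ds = sg.create_dataset(kind, data=wave.y)
            ds.attrs["fs"] = wave.fs
            ds.attrs["t0"] = wave.t[0]


def run_database(ages, out_dir, varied=None, options: SolverOptions | None = None,
                 store_waves: bool = True, reference=None) -> RunManifest:
    """Simulate a (possibly reduced) virtual-subject database.

    ``varied`` restricts the offset grid (default: all six parameters,
    3^6 = 729 subjects per age; e.g. ``("HR",)`` gives a 3-subject test
    grid).  Baseline subjects are simulated first, then the remaining grid
    members.  Per-subject failures are logged and flagged; the run
    continues.  Returns the manifest; writes ``database.h5`` (optional) and
    ``index.csv`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    options = options or SolverOptions()
    reference = reference or load_plausibility_reference()
    from .aging import VARIED_PARAMETERS
    varied = tuple(varied) if varied else VARIED_PARAMETERS
    subjects = generate_grid(ages, varied=varied)
    # baselines first
    subjects.sort(key=lambda s: (not s.is_baseline, s.age))

    manifest = RunManifest()
    index_rows = []
    h5 = h5py.File(out_dir / "database.h5", "a") if store_waves else None
    try:
        for subject in subjects:
            label = subject.label()
            cfg_hash = _config_hash(subject, options)
            if h5 is not None and f"subjects/{label}" in h5 and \
                    h5[f"subjects/{label}"].attrs.get("config_hash") == cfg_hash:
                log.info("skip %s (already simulated)", label)
                continue
            t0 = time.perf_counter()
            row = {"label": label, "age": subject.age,
                   **{f"off_{k}": v for k, v in subject.offsets.items()}}
            try:
                pws, net = simulate_virtual_subject(subject, options=options)
                rep = index_report(pws, net)
                row.update(rep)
                row["converged"] = pws.converged
                row["mass_residual"] = pws.mass_residual
                verdict = plausibility_filter(
                    {k: rep[k] for k in
                     ("aortic_SBP", "aortic_DBP", "aortic_MAP", "aortic_PP",
                      "brachial_SBP", "brachial_DBP", "brachial_MAP",
                      "brachial_PP", "PP_amp")},
                    reference, subject.age)
                row["plausible"] = verdict["plausible"]
                row["violations"] = ";".join(verdict["violations"])
                if h5 is not None:
                    _store_subject(h5, label, pws, subject, cfg_hash)
                row["status"] = "ok"
            except PwdbError as exc:
                log.warning("subject %s failed: %s", label, exc)
                row.update({"status": f"failed: {exc}", "converged": False,
                            "plausible": False})
            row["runtime_s"] = time.perf_counter() - t0
            row["config_hash"] = cfg_hash
            manifest.rows.append(row)
            index_rows.append(row)
            log.info("subject %s done in %.1fs", label, row["runtime_s"])
    finally:
        if h5 is not None:
            h5.close()
    df = pd.DataFrame(index_rows)
    df.to_csv(out_dir / "index.csv", index=False)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_index(out_dir) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "index.csv")


def case3_records(ages, options: SolverOptions | None = None) -> list[dict]:
    """Simulate the single-parameter cohort for the CO-monitoring study.

    Per age: the baseline subject plus HR, SV and MAP at -1/+1 SD (seven
    runs per age).  Returns the record list `co_assess` consumes; reference
    CO is the prescribed HR*SV.
    """
    from .aging import aging_parameters, apply_offsets
    records = []
    for age in ages:
        params = aging_parameters(age)
        combos = [("baseline", {})]
        for p in ("HR", "SV", "MAP"):
            for o in (-1, +1):
                combos.append(("CO" if p in ("HR", "SV") else "MAP", {p: o}))
        for group, offsets in combos:
            subject = apply_offsets(params, offsets)
            pws, _ = simulate_virtual_subject(subject, options=options)
            records.append({
                "age": age, "group": group,
                "radial": pws["radial"]["P"],
                "co_ref": subject.values["HR"] * subject.values["SV"] * 1e-3,
            })
    return records
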