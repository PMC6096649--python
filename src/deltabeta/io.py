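"""Cohort container I/O and EDF reading.

The package's array-container format is one NumPy ``.npz`` file per subject:
one array per condition of shape (n_channels, n_epochs, n_samples), plus a
``_meta`` JSON string holding subject id, group, channel names, condition
order, sampling rate, covariates, and the generating configuration.  A
``cohort.json`` manifest in the same directory lists the subjects and the
cohort-level provenance.

EDF reading (for user-supplied cleaned recordings) goes through MNE and is
imported lazily so the core analysis has no hard MNE dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import SubjectData, SyntheticCohort

__all__ = ["save_cohort", "load_cohort", "read_edf"]


def save_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to ``outdir`` (one .npz per subject plus a manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject in cohort.subjects:
        meta = {
            "subject_id": subject.subject_id,
            "group": subject.group,
            "channels": list(cohort.channels),
            "conditions": list(cohort.conditions),
            "sampling_rate": cohort.sampling_rate,
            "covariates": subject.covariates,
            "coupling_scale": subject.coupling_scale,
        }
        arrays = {cond: subject.data[cond] for cond in cohort.conditions}
        np.savez(
            outdir / f"{subject.subject_id}.npz",
            _meta=np.array(json.dumps(meta)),
            **arrays,
        )
    manifest = {
        "subjects": [s.subject_id for s in cohort.subjects],
        "channels": list(cohort.channels),
        "conditions": list(cohort.conditions),
        "sampling_rate": cohort.sampling_rate,
        "provenance": cohort.provenance,
    }
    (outdir / "cohort.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def load_cohort(indir: str | Path) -> SyntheticCohort:
    """Load a cohort written by :func:`save_cohort`."""
    indir = Path(indir)
    manifest_path = indir / "cohort.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    subjects = []
    for sid in manifest["subjects"]:
        path = indir / f"{sid}.npz"
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["_meta"]))
            data = {cond: npz[cond] for cond in meta["conditions"]}
        subjects.append(
            SubjectData(
                subject_id=meta["subject_id"],
                group=meta["group"],
                data=data,
                covariates=meta.get("covariates", {}),
                coupling_scale=meta.get("coupling_scale", 1.0),
            )
        )
    return SyntheticCohort(
        subjects=subjects,
        channels=tuple(manifest["channels"]),
        conditions=tuple(manifest["conditions"]),
        sampling_rate=manifest["sampling_rate"],
        provenance=manifest.get("provenance", {}),
    )


def read_edf(path: str | Path, channels: list[str] | None = None):
    """Read an EDF recording; returns (data, sampling_rate, channel_names).

    ``data`` has shape (n_channels, n_samples).  Requires MNE.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
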