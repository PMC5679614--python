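"""File-format boundary: NIfTI volumes, sidecar metadata, and TSV tables.

Conventions: multi-echo data travel as paired magnitude/phase NIfTI files
with a JSON sidecar carrying ``EchoTimes`` (seconds); all tabular output is
tab-separated UTF-8 with a header row and ``NA`` for missing values.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

NA = "NA"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_multiecho(magnitude, phase, affine, echo_times, stem: Path) -> dict:
    """Write magnitude/phase 4D NIfTI pair plus the echo-time sidecar.

    Returns the paths written, keyed mag/phase/sidecar.
    """
    stem = Path(stem)
    paths = {
        "mag": stem.with_name(stem.name + "_mag.nii"),
        "phase": stem.with_name(stem.name + "_phase.nii"),
        "sidecar": stem.with_name(stem.name + ".json"),
    }
    save_nifti(np.asarray(magnitude, dtype=np.float32), affine, paths["mag"])
    save_nifti(np.asarray(phase, dtype=np.float32), affine, paths["phase"])
    paths["sidecar"].write_text(
        json.dumps({"EchoTimes": [float(t) for t in echo_times]}, indent=1)
    )
    return paths


def load_multiecho(stem: Path) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Read a magnitude/phase pair back into a complex 4D array."""
    stem = Path(stem)
    mag, affine = load_nifti(stem.with_name(stem.name + "_mag.nii"))
    phase, _ = load_nifti(stem.with_name(stem.name + "_phase.nii"))
    meta = json.loads(stem.with_name(stem.name + ".json").read_text())
    data = mag.astype(np.float64) * np.exp(1j * phase.astype(np.float64))
    return data, affine, [float(t) for t in meta["EchoTimes"]]
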