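"""Plain-text readers and writers for the analysis inputs and outputs.

All file dialects are diffable text: TSV for samples, curves and
profiles; JSON for results; PDB for structures (see
:mod:`porefep.geometry`).  The packaged affinity table ships the
printed per-ligand free-energy components, totals, dissociation
constants and predicted IC50 ranges used throughout the tests and the
worked examples.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .fep import WindowSamples
from .poreblock import DoseResponse

_AFFINITY_TABLE = "glic_affinity_table.tsv"


def load_affinity_table() -> pd.DataFrame:
    """Packaged per-ligand, per-site affinity table.

    Columns: anesthetic, site, conformation, the free-energy components
    (dG_solv, dG_sym, dG_V, kcal/mol), the totals with standard errors
    (dG_bind1/2), dissociation constants (kd1_uM, kd2_uM), the
    predicted IC50 range (ic50_range_uM, "low-high" string) and the
    experimental IC50 (exp_ic50_uM).  The ethanol kd1 entry is the
    narrative 510 mM value and is an annotation, not a validated
    target.
    """
    with resources.files("porefep.data").joinpath(_AFFINITY_TABLE).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def parse_ic50_range(cell: str) -> tuple:
    """Split an "low-high" IC50 range cell into two floats."""
    low, high = str(cell).split("-")
    return float(low), float(high)


# ---------------------------------------------------------------------------
# FEP window samples

def write_window_samples(windows: Iterable[WindowSamples], path) -> None:
    """TSV with columns lambda_low, lambda_high, direction, delta_u."""
    rows = []
    for w in windows:
        for du in w.forward_du:
            rows.append((w.lambda_low, w.lambda_high, "forward", du))
        for du in w.backward_du:
            rows.append((w.lambda_low, w.lambda_high, "backward", du))
    df = pd.DataFrame(rows, columns=["lambda_low", "lambda_high", "direction", "delta_u"])
    df.to_csv(path, sep="\t", index=False)


def read_window_samples(path) -> list:
    """Read the TSV window-sample dialect back into ``WindowSamples``."""
    df = pd.read_csv(path, sep="\t")
    required = {"lambda_low", "lambda_high", "direction", "delta_u"}
    if not required.issubset(df.columns):
        raise ValidationError(f"window sample file needs columns {sorted(required)}")
    windows = []
    for (lo, hi), grp in df.groupby(["lambda_low", "lambda_high"], sort=True):
        fwd = grp.loc[grp.direction == "forward", "delta_u"].to_numpy()
        bwd = grp.loc[grp.direction == "backward", "delta_u"].to_numpy()
        windows.append(WindowSamples(lambda_low=lo, lambda_high=hi,
                                     forward_du=fwd, backward_du=bwd))
    return windows


def read_fepout(path) -> list:
    """Lenient reader for a NAMD-style per-window work file.

    Windows are introduced by a comment line

        # window <lambda_low> <lambda_high> <forward|backward>

    followed by whitespace-separated data lines whose *last* column is
    the energy difference (a leading time/step column is ignored, as
    are blank lines and other comment lines).
    """
    blocks = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) >= 4 and parts[0].lower() == "window":
                    lo, hi, direction = float(parts[1]), float(parts[2]), parts[3].lower()
                    if direction not in ("forward", "backward"):
                        raise ValidationError(f"unknown direction {direction!r}")
                    current = blocks.setdefault((lo, hi), {"forward": [], "backward": []})[direction]
                continue
            if current is None:
                continue
            try:
                current.append(float(line.split()[-1]))
            except ValueError:
                continue  # lenient: skip malformed lines
    if not blocks:
        raise ValidationError(f"no windows found in {path}")
    return [
        WindowSamples(lambda_low=lo, lambda_high=hi,
                      forward_du=np.asarray(b["forward"]),
                      backward_du=np.asarray(b["backward"]))
        for (lo, hi), b in sorted(blocks.items())
    ]


# ---------------------------------------------------------------------------
# Dose-response curves

def write_dose_response(data: DoseResponse, path) -> None:
    pd.DataFrame(
        {"concentration": data.concentrations, "inhibition": data.inhibition}
    ).to_csv(path, sep="\t", index=False)


def read_dose_response(path) -> DoseResponse:
    df = pd.read_csv(path, sep="\t")
    if not {"concentration", "inhibition"}.issubset(df.columns):
        raise ValidationError("dose file needs columns concentration, inhibition")
    return DoseResponse(
        concentrations=df["concentration"].to_numpy(),
        inhibition=df["inhibition"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Trajectories and profiles

def write_ligand_com(frames_xyz: np.ndarray, path) -> None:
    """CSV of ligand center-of-mass coordinates.

    ``frames_xyz``: array (n_frames, n_ligands, 3); written with
    columns frame, ligand_id, x, y, z.
    """
    arr = np.asarray(frames_xyz, dtype=float)
    n_frames, n_lig, _ = arr.shape
    rows = [
        (t, i, *arr[t, i]) for t in range(n_frames) for i in range(n_lig)
    ]
    pd.DataFrame(rows, columns=["frame", "ligand_id", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_ligand_com(path) -> np.ndarray:
    """Inverse of :func:`write_ligand_com`; returns (n_frames, n_ligands, 3)."""
    df = pd.read_csv(path)
    required = {"frame", "ligand_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(f"ligand COM file needs columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    ligands = np.sort(df["ligand_id"].unique())
    out = np.full((frames.size, ligands.size, 3), np.nan)
    fi = {f: i for i, f in enumerate(frames)}
    li = {l: i for i, l in enumerate(ligands)}
    for row in df.itertuples(index=False):
        out[fi[row.frame], li[row.ligand_id]] = (row.x, row.y, row.z)
    return out


def write_z_series(z: np.ndarray, path) -> None:
    """Single-column axial position series (one value per line)."""
    np.savetxt(path, np.asarray(z, dtype=float).ravel(), fmt="%.8g")


def read_z_series(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def write_profile_tsv(centers: np.ndarray, values: np.ndarray, path,
                      value_name: str = "value") -> None:
    pd.DataFrame({"center": centers, value_name: values}).to_csv(
        path, sep="\t", index=False
    )


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Provenance

def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance(seed: Optional[int] = None, inputs: Sequence = ()) -> dict:
    """Provenance block attached to JSON outputs."""
    return {
        "porefep_version": __version__,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }


def dump_json(payload: dict, path=None) -> str:
    text = json.dumps(payload, indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
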