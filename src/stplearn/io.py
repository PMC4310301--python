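"""Persistence: columnar text for rasters/time series, npz for state arrays."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import tm
from .network import SimState

__all__ = [
    "write_raster",
    "read_raster",
    "save_state_arrays",
    "load_state_arrays",
    "write_run_tables",
]

_STATE_KEYS = ("U", "tau_rec", "tau_facil", "A", "r", "u", "v", "nu", "mask")


def write_raster(raster: pd.DataFrame, path) -> None:
    """Spike raster as tab-separated (time_ms, neuron_id) with header."""
    raster.to_csv(path, sep="\t", index=False)


def read_raster(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_state_arrays(state: SimState, path) -> None:
    """Self-describing array container (npz keyed by array name)."""
    np.savez(
        path,
        U=state.stp_params.U,
        tau_rec=state.stp_params.tau_rec,
        tau_facil=state.stp_params.tau_facil,
        A=state.A,
        r=state.stp.r,
        u=state.stp.u,
        v=state.neurons.v,
        nu=state.rates.nu,
        mask=state.spec.mask,
    )


def load_state_arrays(path) -> dict:
    """Load a saved state container back into a dict of arrays."""
    with np.load(path) as data:
        return {k: data[k] for k in data.files}


def write_run_tables(result, outdir) -> None:
    """Rates / symmetry / parameter time series as TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.rates.rename_axis("time_s").to_csv(outdir / "rates.tsv", sep="\t")
    result.symmetry.rename_axis("time_s").to_csv(outdir / "symmetry.tsv", sep="\t")
    result.params.rename_axis("time_s").to_csv(outdir / "params.tsv", sep="\t")
    if result.raster is not None:
        write_raster(result.raster, outdir / "raster.tsv")
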