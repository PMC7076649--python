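"""Golden-fixture generator for regression testing.

Writes deterministic tabulations (structure, landscape summaries,
timescales) for a pinned set of state points; repeated runs on the same
grids are byte-identical, so the output doubles as a regression anchor.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EcnleError
from .free_energy import locate_extrema
from .kinetics import MATERIALS, MaterialModel, compute_timescales
from .structure import FluidState, compute_structure

#: default pinned (phi, pstar) states
PINNED_STATES: tuple[tuple[float, float], ...] = (
    (0.50, 0.0),
    (0.55, 0.0),
    (0.55, 1.8),
    (0.58, 2.6),
)


def _fmt(x: float) -> float:
    # round-trip-stable decimal representation for byte-identical JSON
    return float(f"{x:.12g}")


def generate_fixtures(
    outdir: str | Path,
    pinned_states=PINNED_STATES,
    material: MaterialModel | None = None,
) -> dict:
    """Write structure/landscape/timescale fixtures for the pinned states.

    Per-state regime failures (e.g. no barrier below the arrest onset)
    are recorded in the manifest rather than raised.  Returns the
    manifest dict; files land under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    material = material or MATERIALS["curcumin"]
    manifest: dict = {"material": material.name, "states": []}

    for phi, pstar in pinned_states:
        tag = f"phi{phi:.2f}_p{pstar:g}"
        entry: dict = {"phi": phi, "pstar": pstar, "tag": tag}
        try:
            structure = compute_structure(phi)
            state = FluidState(phi, pstar)

            sq = pd.DataFrame({"q": structure.q_grid, "s_of_q": structure.s_of_q})
            gr = pd.DataFrame({"r": structure.r_grid, "g_of_r": structure.g_of_r})
            # thin the tables: every 8th point is plenty for regression
            sq.iloc[::8].to_csv(outdir / f"sq_{tag}.csv", index=False, float_format="%.10g")
            gr.iloc[::8].to_csv(outdir / f"gr_{tag}.csv", index=False, float_format="%.10g")

            profile = locate_extrema(state, structure)
            ts = compute_timescales(state, structure, material)
            entry["summary"] = {
                "r_cage": _fmt(structure.r_cage),
                "g_contact": _fmt(structure.g_contact),
                "r_loc": _fmt(profile.r_loc),
                "r_barrier": _fmt(profile.r_barrier),
                "f_barrier": _fmt(profile.f_barrier),
                "k0": _fmt(profile.k0),
                "kb_curv": _fmt(profile.kb_curv),
                "log10_tau_s": _fmt(np.log10(ts.tau_s)),
                "log10_tau_alpha": _fmt(np.log10(ts.tau_alpha)),
                "log10_tau_beta": _fmt(np.log10(ts.tau_beta)),
            }
        except EcnleError as exc:
            entry["error"] = f"{type(exc).__name__}: {exc}"
        manifest["states"].append(entry)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
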