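"""Synthetic input bundle: topologies, calibrated parameter files, toy
circuits with analytic ground truth, and seeded example trajectories.

Everything a run of the pipeline reads is generated here, deterministically
from one master seed; a manifest records the per-file sub-seeds and SHA-256
checksums so any fixture can be regenerated and verified independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import topology as topo
from .model import find_steady_states, simulate
from .params import (
    default_core_parameters,
    default_coupled_parameters,
    write_parameters,
)

#: sub-seed scheme: master * 1000 + counter, kept below 2**31
def subseed(master: int, counter: int) -> int:
    return (master * 1000 + counter) % 2**31


@dataclass
class FixtureBundle:
    directory: Path
    manifest: dict

    def path(self, name: str) -> Path:
        return self.directory / name


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def toggle_ground_truth(grid_n: int = 200) -> np.ndarray:
    """Stable states of the shipped deterministic toggle switch found by
    brute-force relaxation from a grid (recomputed, never stored)."""
    from .ensemble import SampledModel, solve_model

    m = SampledModel(g=np.array([50.0, 50.0]), k=np.array([0.5, 0.5]),
                     lam=np.array([0.02, 0.02]), n=np.array([4, 4]),
                     threshold=np.array([60.0, 60.0]))
    rng = np.random.default_rng(0)
    states = solve_model(topo.toggle_switch(), m, grid_n, rng)
    return states


def generate_fixtures(out_dir: str | Path, master_seed: int = 1729,
                      force: bool = False) -> FixtureBundle:
    """Write the full bundle; refuses to overwrite a non-empty directory
    unless ``force`` is set."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    files: dict[str, dict] = {}

    def record(name: str, seed: int | None = None) -> None:
        files[name] = {"sha256": _sha256(out / name), "seed": seed}

    # --- topologies -----------------------------------------------------
    for t, name in [(topo.wildtype_coupled(), "coupled.topo"),
                    (topo.core_emt(), "core.topo"),
                    (topo.single_node(), "single_node.topo"),
                    (topo.toggle_switch(), "toggle.topo")]:
        topo.write_topo(t, out / name)
        record(name)

    # --- calibrated mechanistic parameters ------------------------------
    write_parameters(default_coupled_parameters(), out / "params_coupled.tsv")
    record("params_coupled.tsv")
    write_parameters(default_core_parameters(), out / "params_core.tsv")
    record("params_core.tsv")

    # --- double-well toy (analytic ground truth in the file itself) -----
    dw = {"kind": "double_well", "center": 2.0, "half_width": 1.0,
          "stiffness": 4.0, "y_center": 1.0, "y_rate": 1.0,
          "wells": [1.0, 3.0], "separatrix_x": 2.0,
          "barrier_height_deterministic": 1.0}
    (out / "double_well.json").write_text(json.dumps(dw, indent=1))
    record("double_well.json")

    # --- seeded example trajectory (epithelial start, EMT-inducing S) ---
    seed_traj = subseed(master_seed, 1)
    p0 = default_core_parameters(0.0)
    e0 = [s for s in find_steady_states(p0, n_starts=8, seed=seed_traj)
          if s.stable][0].state
    tr = simulate(e0, default_core_parameters(330e3), t_max=500.0,
                  n_points=251)
    frame = pd.DataFrame(tr.states, columns=list(tr.species))
    frame.insert(0, "time", tr.times)
    frame.to_csv(out / "example_trajectory_core.csv", index=False,
                 float_format="%.6g")
    record("example_trajectory_core.csv", seed_traj)

    manifest = {"master_seed": master_seed,
                "subseed_scheme": "master*1000 + counter, mod 2^31",
                "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return FixtureBundle(directory=out, manifest=manifest)
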