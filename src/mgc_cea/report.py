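"""Report assembly: machine-readable tables and a run manifest.

Turns the analyses into the files a reviewer or downstream script consumes:
the three-strategy base-case outcome table, the incremental comparisons,
tornado / PSA / CEAC / budget CSVs, and a manifest recording the config
hash, seeds and every emitted file so a run is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .budget import project_budget
from .cohort import STRATEGIES, run_all_strategies
from .econ import (
    DEFAULT_WTP_GRID,
    ceac,
    compute_icer,
    one_way_sensitivity,
    run_psa,
    tornado_frame,
)
from .parameters import ModelInputs, dump_inputs, load_inputs

logger = logging.getLogger(__name__)


def config_hash(path: str | Path | None) -> str:
    """SHA-256 of the config file bytes (packaged base case when path is None)."""
    if path is None:
        from importlib import resources

        data = resources.files("mgc_cea").joinpath("data/base_case.yaml").read_bytes()
    else:
        data = Path(path).read_bytes()
    return hashlib.sha256(data).hexdigest()


@dataclass
class RunManifest:
    config_sha256: str
    seed: int | None = None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    files: list = field(default_factory=list)

    def record(self, path: Path) -> Path:
        self.files.append(path.name)
        return path

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        path.write_text(
            json.dumps(
                {
                    "config_sha256": self.config_sha256,
                    "seed": self.seed,
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "files": sorted(self.files),
                },
                indent=2,
            )
        )
        return path


def outcome_table(summaries: dict) -> pd.DataFrame:
    """Three-strategy outcome table, one row per quantity (base-case layout)."""
    rows = [
        ("cost_pfs_state", lambda s: s.costs.cost_pfs_state),
        ("cost_pd_state", lambda s: s.costs.cost_pd_state),
        ("cost_death", lambda s: s.costs.cost_death),
        ("total_cost", lambda s: s.total_cost),
        ("disease_free_ly", lambda s: s.disease_free_ly),
        ("overall_ly", lambda s: s.overall_ly),
        ("qalys", lambda s: s.qalys),
    ]
    return pd.DataFrame(
        {"quantity": [name for name, _ in rows]}
        | {strat: [get(summaries[strat]) for _, get in rows] for strat in STRATEGIES}
    )


def incremental_results(summaries: dict) -> dict:
    """Both incremental comparisons against control, on QALYs and LYs."""
    out = {}
    for alt in ("apatinib_no_pap", "apatinib_pap"):
        q = compute_icer(summaries["control"], summaries[alt], "qalys")
        l = compute_icer(summaries["control"], summaries[alt], "ly")
        out[alt] = {
            "delta_cost": q.delta_cost,
            "delta_qalys": q.delta_effect,
            "delta_ly": l.delta_effect,
            "icer_per_qaly": q.icer,
            "icer_per_ly": l.icer,
            "dominance": q.dominance,
        }
    return out


def run_base_case(
    config_path: str | Path | None, out_dir: str | Path
) -> RunManifest:
    """Emit table3.csv (three-strategy outcomes), icers.json and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config_path)
    manifest = RunManifest(config_sha256=config_hash(config_path))
    summaries = run_all_strategies(inputs)

    outcome_table(summaries).to_csv(manifest.record(out / "table3.csv"), index=False)
    manifest.record(out / "icers.json").write_text(
        json.dumps(incremental_results(summaries), indent=2)
    )
    dump_inputs(inputs, manifest.record(out / "inputs_resolved.yaml"))
    manifest.write(out)
    logger.info("base case written to %s", out)
    return manifest


def run_full(
    config_path: str | Path | None,
    out_dir: str | Path,
    n: int = 1000,
    seed: int = 0,
    wtp_max: float = 60000.0,
) -> RunManifest:
    """Orchestrate every analysis; adds tornado, PSA, CEAC and budget files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config_path)
    manifest = run_base_case(config_path, out)
    manifest.seed = seed

    entries = one_way_sensitivity(inputs, ("control", "apatinib_pap"))
    tornado_frame(entries).to_csv(manifest.record(out / "tornado.csv"), index=False)

    psa = run_psa(inputs, n=n, seed=seed)
    psa.draws.to_csv(manifest.record(out / "psa.csv"), index=False)

    grid = [w for w in DEFAULT_WTP_GRID if w <= wtp_max]
    curves = []
    for alt in ("apatinib_no_pap", "apatinib_pap"):
        curve = ceac(psa, grid, ("control", alt)).to_frame()
        curve.insert(0, "strategy", alt)
        curves.append(curve)
    pd.concat(curves).to_csv(manifest.record(out / "ceac.csv"), index=False)

    project_budget(inputs).to_csv(manifest.record(out / "budget.csv"))
    manifest.write(out)
    logger.info("full analysis written to %s", out)
    return manifest
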