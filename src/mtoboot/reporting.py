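"""Run manifests: bind every ensemble output to its full provenance.

A manifest records the generator configuration, the ensemble configuration
(seed grids, draw counts, M), the replication-cell estimate, and SHA-256
digests of every output file. Replaying a manifest reruns the whole
pipeline from the recorded configuration and verifies the digests; because
every stage is a pure function of its seeds, a clean replay is
byte-identical, and any divergence is localized to the cells whose
coordinates changed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .ensemble import (
    EnsembleCell,
    EnsembleConfig,
    cells_to_frame,
    plot_ensemble,
    run_coefficient_ensemble,
    run_specification_ensemble,
    summarize_ensemble,
)
from .model import ORIGINAL_SPEC, fit_model
from .synthetic import (
    GeneratorConfig,
    config_from_yaml,
    config_to_yaml,
    generate_target_cohort,
    generate_training,
)

__all__ = ["RunManifest", "run_pipeline", "write_manifest", "read_manifest", "replay"]

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles; digests see full precision


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    generator_config_yaml: str
    ensemble_config: dict
    cell_count: int
    replication_cell: dict
    output_digests: dict[str, str]
    package_version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        return cls(**d)


@dataclass
class RunResult:
    manifest: RunManifest
    cells: list[EnsembleCell]
    summary: dict
    out_dir: Path


def run_pipeline(
    gen_config: GeneratorConfig,
    ens_config: EnsembleConfig,
    out_dir,
    make_figure: bool = True,
) -> RunResult:
    """Run the full pipeline and write its outputs under ``out_dir``.

    Generates the training sample and target cohort, fits the imputation
    model under the original specification, runs the configured ensemble,
    and writes ``cells.csv``, ``summary.json``, ``config.yaml``,
    ``ensemble.svg`` (optional) and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    training = generate_training(gen_config)
    cohort = generate_target_cohort(gen_config)
    if ens_config.mode == "coefficient_resampling":
        fitted = fit_model(training, ORIGINAL_SPEC)
        cells = run_coefficient_ensemble(cohort, fitted, ens_config)
    else:
        cells = run_specification_ensemble(training, cohort, ens_config)
    summary = summarize_ensemble(cells)

    cfg_path = out_dir / "config.yaml"
    gen_yaml = config_to_yaml(gen_config, cfg_path)
    cells_path = out_dir / "cells.csv"
    cells_to_frame(cells).to_csv(cells_path, index=False, float_format=_FLOAT_FMT)
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    outputs = [cfg_path, cells_path, summary_path]
    if make_figure:
        fig_path = out_dir / "ensemble.svg"
        plot_ensemble(cells, fig_path)
        outputs.append(fig_path)

    digests = {p.name: _sha256(p) for p in outputs}
    manifest = RunManifest(
        generator_config_yaml=gen_yaml,
        ensemble_config=dataclasses.asdict(ens_config),
        cell_count=len(cells),
        replication_cell=summary.get("replication_cell", {}),
        output_digests=digests,
    )
    write_manifest(manifest, out_dir / "manifest.json")
    return RunResult(manifest, cells, summary, out_dir)


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)


def read_manifest(path) -> RunManifest:
    with open(path) as fh:
        return RunManifest.from_dict(json.load(fh))


def _diff_cells(recorded_path, replayed_path) -> list[dict]:
    """Localize a cells.csv divergence to the differing grid coordinates."""
    key = ["index", "pr_seed", "mi_seed", "arm_contrast"]
    a = pd.read_csv(recorded_path).set_index(key).sort_index()
    b = pd.read_csv(replayed_path).set_index(key).sort_index()
    diffs = []
    common = a.index.intersection(b.index)
    for idx in a.index.symmetric_difference(b.index):
        diffs.append({"cell": list(idx), "reason": "present in only one run"})
    for idx in common:
        ra, rb = a.loc[idx], b.loc[idx]
        if not ra.equals(rb):
            diffs.append({"cell": list(idx), "reason": "values differ"})
    return diffs


def replay(manifest_path, out_dir) -> dict:
    """Re-execute a recorded run and verify its output digests.

    Returns a divergence report: ``{"match": bool, "diverged": [files],
    "cell_divergences": [...]}``. An exact replay reports zero divergences;
    a perturbed configuration localizes the damage to the affected cells.
    """
    manifest = read_manifest(manifest_path)
    gen_config = config_from_yaml(manifest.generator_config_yaml)
    ens_config = EnsembleConfig(**manifest.ensemble_config)
    make_figure = "ensemble.svg" in manifest.output_digests
    result = run_pipeline(gen_config, ens_config, out_dir, make_figure=make_figure)

    diverged = []
    for name, digest in manifest.output_digests.items():
        replayed = Path(out_dir) / name
        if not replayed.exists() or _sha256(replayed) != digest:
            diverged.append(name)
    report = {
        "match": not diverged,
        "diverged": diverged,
        "cell_divergences": [],
        "replayed_manifest": result.manifest.to_dict(),
    }
    if "cells.csv" in diverged:
        recorded_dir = Path(manifest_path).parent
        recorded_cells = recorded_dir / "cells.csv"
        if recorded_cells.exists():
            report["cell_divergences"] = _diff_cells(
                recorded_cells, Path(out_dir) / "cells.csv"
            )
    return report
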