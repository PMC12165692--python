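"""Run configuration, seed fan-out and provenance.

One :class:`RunConfig` holds every tunable parameter of both workflows with
the documented defaults.  A single ``master_seed`` fans out to per-stage
seeds through a stable hash of the stage name, so partial re-runs of a
pipeline stay consistent with full runs.  Every workflow writes the
resolved config, its content hash, the package version and the derived
seeds next to its outputs — enough to replay the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    # -- inputs / outputs --
    source_path: str | None = None
    target_path: str | None = None
    labels_path: str | None = None
    survival_expr_path: str | None = None
    survival_table_path: str | None = None
    model_path: str | None = None
    outdir: str = "cellvec_out"

    # -- preprocessing --
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 20
    n_top_hvg: int = 2000
    unit: str = "umi"

    # -- embedding (PV-DM) --
    dim: int = 300
    window: int = 5
    initial_lr: float = 0.025
    min_count: int = 1
    epochs_pretrain: int = 40
    epochs_finetune: int = 10
    infer_epochs: int = 50

    # -- clustering / visualization --
    leiden_resolution: float = 1.0
    n_neighbors: int = 15
    resolutions: list[float] = field(
        default_factory=lambda: [round(0.2 * k, 1) for k in range(1, 11)]
    )

    # -- phenotype algebra --
    algebra_queries: list[str] = field(default_factory=list)
    smote_k: int = 5
    n_boot: int = 50
    train_frac: float = 0.8
    n_estimators: int = 1000
    rsf_min_samples_leaf: int = 20
    min_common_genes: int = 50

    # -- reproducibility --
    master_seed: int = 0

    # ------------------------------------------------------------------
    def seed_for(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        key = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
        return int(np.random.SeedSequence([self.master_seed, key]).generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    _PATH_FIELDS = ("source_path", "target_path", "labels_path",
                    "survival_expr_path", "survival_table_path",
                    "model_path", "outdir")

    def content_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded, so the same
        analysis run into two directories carries the same hash)."""
        d = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(config: RunConfig, outdir: str | Path, stages: list[str]) -> None:
    """Resolved config + hash + version + derived seeds, for exact replay."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "resolved_config.json")
    meta = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {s: config.seed_for(s) for s in stages},
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def attach_logfile(outdir: str | Path) -> logging.Handler:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("cellvec").addHandler(handler)
    logging.getLogger("cellvec").setLevel(logging.INFO)
    return handler
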