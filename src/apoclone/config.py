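"""Run configuration: a YAML file binding paths, stage parameters and the
global seed.  The global seed fans out to per-stage seeds by fixed offsets so
stages rerun independently yet reproducibly."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clonality import assess_clonality  # noqa: F401  (re-export convenience)
from .landscape import WindowThresholds
from .markers import MarkerFilterParams
from .flow import PloidyCallParams

# fixed per-stage seed offsets (kept small so seed + offset stays < 2**31)
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "markers": 101,
    "landscape": 202,
    "flow": 303,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "apoclone_out"
    vcf: str | None = None
    manifest: str | None = None
    chrom_table: str | None = None
    masks: list[str] = field(default_factory=list)
    markers: str | None = None           # precomputed marker TSV (skips selection)
    histograms_dir: str | None = None    # per-sample <sample>.tsv flow histograms
    control_2c_channel: float | None = None
    event_of: dict[str, str] = field(default_factory=dict)  # sample -> event id
    marker_filter: MarkerFilterParams = field(default_factory=MarkerFilterParams)
    window: int = 200_000
    step: int = 100_000
    thresholds: WindowThresholds = field(default_factory=WindowThresholds)
    smooth: bool = True
    clonal_min_het: float = 0.99
    ploidy_params: PloidyCallParams = field(default_factory=PloidyCallParams)
    chimeric_as: str = "tetraploid"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "output_dir", "vcf", "manifest", "chrom_table", "masks",
                    "markers", "histograms_dir", "control_2c_channel", "event_of",
                    "window", "step", "smooth", "clonal_min_het", "chimeric_as",
                    "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "marker_filter" in raw:
            kwargs["marker_filter"] = MarkerFilterParams(**raw["marker_filter"])
        if "thresholds" in raw:
            kwargs["thresholds"] = WindowThresholds(**raw["thresholds"])
        if "ploidy_params" in raw:
            kwargs["ploidy_params"] = PloidyCallParams(**raw["ploidy_params"])
        cfg = cls(**kwargs)
        cfg.validate_static()
        return cfg

    def validate_static(self) -> None:
        if self.step < 1 or self.window < self.step:
            raise ValueError("require window >= step >= 1")
        if not 0.0 < self.clonal_min_het <= 1.0:
            raise ValueError("clonal_min_het must lie in (0, 1]")

    def require_paths(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            values = value if isinstance(value, list) else [value]
            for v in values:
                if v is None:
                    raise FileNotFoundError(f"config is missing required path '{name}'")
                if not Path(v).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {v}")
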