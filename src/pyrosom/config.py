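"""Pipeline configuration: one flat parameter set with workflow defaults.

Defaults reproduce the standard parameterization of the workflow: EIC
intensity threshold 1e5, S/N >= 5, minimum feature height 1e5, 0.05 min
retention-time tolerance, 0.7 thresholds for alignment, annotation and
network edges, TopK 10, 999 PERMANOVA permutations, and an EGA program of
100 -> 900 °C at 10 °C/min after a 1 min hold with a 650 °C
inorganic-carbon cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ParameterError


@dataclass
class PipelineConfig:
    intensity_threshold: float = 1e5
    min_sn: float = 5.0
    min_height: float = 1e5
    rt_tol: float = 0.05           # minutes
    apex_gap: float = 0.01         # minutes, component split inside a window
    align_threshold: float = 0.7
    w_rt: float = 0.5
    annotate_min_cosine: float = 0.7
    network_min_cosine: float = 0.7
    propagate_min_cosine: float | None = None  # defaults to network threshold
    topk: int = 10
    n_perm: int = 999
    ega_start_temp: float = 100.0  # °C
    ega_hold: float = 1.0          # minutes
    ega_ramp_rate: float = 10.0    # °C/min
    ega_end_temp: float = 900.0    # °C
    ega_smooth_window: int = 5     # scans
    ic_cutoff: float = 650.0       # °C
    co2_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.intensity_threshold > 0, "intensity_threshold must be > 0"),
            (self.min_sn >= 1, "min_sn must be >= 1"),
            (self.min_height > 0, "min_height must be > 0"),
            (self.rt_tol > 0, "rt_tol must be > 0"),
            (0 < self.apex_gap <= self.rt_tol,
             "apex_gap must be in (0, rt_tol]"),
            (0 < self.align_threshold <= 1,
             "align_threshold must be in (0, 1]"),
            (0 <= self.w_rt <= 1, "w_rt must be in [0, 1]"),
            (0 < self.annotate_min_cosine <= 1,
             "annotate_min_cosine must be in (0, 1]"),
            (0 < self.network_min_cosine <= 1,
             "network_min_cosine must be in (0, 1]"),
            (self.topk >= 1, "topk must be >= 1"),
            (self.n_perm >= 1, "n_perm must be >= 1"),
            (self.ega_end_temp > self.ega_start_temp,
             "ega_end_temp must exceed ega_start_temp"),
            (self.ega_ramp_rate > 0, "ega_ramp_rate must be > 0"),
            (self.ega_smooth_window >= 1, "ega_smooth_window must be >= 1"),
            (0 < self.co2_ratio < 1, "co2_ratio must be in (0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat ``key = value`` config file ('#' starts a comment)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(
                    f"{path}:{lineno}: expected 'key = value', got {line!r}"
                )
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ParameterError(f"{path}:{lineno}: unknown parameter {key!r}")
            ftype = fields[key].type
            try:
                if "int" in str(ftype):
                    kwargs[key] = int(value)
                elif value.lower() == "none":
                    kwargs[key] = None
                else:
                    kwargs[key] = float(value)
            except ValueError as exc:
                raise ParameterError(
                    f"{path}:{lineno}: bad value {value!r} for {key!r}"
                ) from exc
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_dict(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")
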