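"""Pipeline configuration: tolerances, rule thresholds, simulation defaults.

Defaults mirror a standard ion-trap phosphopeptide search: precursor
tolerance 10 ppm, fragment tolerance 0.5 Da, acceptance score threshold
20, and a consecutive-ion requirement of 4 in each backbone series.

Config files are flat ``key = value`` text; unknown keys are hard errors
so that a misspelled threshold can never silently weaken the rule engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    prec_tol_ppm: float = 10.0
    frag_tol_da: float = 0.5
    abundance_floor: float = 0.05
    score_threshold: float = 20.0
    consecutive_rule_mode: str = "both"  # "both" | "either"
    run_length_min: int = 4
    enable_h2o_loss: bool = False
    enable_nh3_loss: bool = False
    default_charge: int = 2
    seed: int = 0
    # simulation defaults
    sim_dropout_prob: float = 0.0
    sim_noise_peaks: int = 20
    sim_mass_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        checks = {
            "prec_tol_ppm": self.prec_tol_ppm > 0,
            "frag_tol_da": self.frag_tol_da > 0,
            "abundance_floor": 0 <= self.abundance_floor < 1,
            "score_threshold": self.score_threshold >= 0,
            "consecutive_rule_mode": self.consecutive_rule_mode in ("both", "either"),
            "run_length_min": self.run_length_min >= 1,
            "default_charge": self.default_charge >= 1,
            "sim_dropout_prob": 0 <= self.sim_dropout_prob <= 1,
            "sim_noise_peaks": self.sim_noise_peaks >= 0,
            "sim_mass_jitter_sd": self.sim_mass_jitter_sd >= 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration value(s) for: {', '.join(bad)}")

    @property
    def losses(self) -> tuple[str, ...]:
        out = []
        if self.enable_h2o_loss:
            out.append("minus_H2O")
        if self.enable_nh3_loss:
            out.append("minus_NH3")
        return tuple(out)

    def to_text(self) -> str:
        return "".join(
            f"{f.name} = {getattr(self, f.name)}\n" for f in fields(self)
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key = value config file. Unknown keys are errors."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    defaults = PipelineConfig()
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        current = getattr(defaults, key)
        if isinstance(current, bool):
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif isinstance(current, int):
            kwargs[key] = int(value)
        elif isinstance(current, float):
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
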