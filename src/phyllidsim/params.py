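"""Scenario parameter schema and shipped calibrated defaults.

The parameter set controls the three developmental phases, positional
zonation, growth-rate assignment, cell division and the midrib.  The five
scenario presets (wild-type upper phyllid, *pina pinb* mutant, auxin-treated
wild type, auxin-treated mutant, basal phyllid) differ only in a handful of
deltas, all loaded from version-controlled YAML files shipped with the
package (``phyllidsim/params/<scenario>.yaml``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import yaml

SCENARIOS = ("wt_upper", "pina_pinb", "auxin_wt", "auxin_pina_pinb", "basal")


@dataclass
class ScenarioParams:
    """All tunable model parameters (times in days, lengths in µm)."""

    scenario: str = "wt_upper"
    # --- timeline
    t0_days: float = 1.0           # template corresponds to day 1
    t_end_days: float = 5.5
    dt_days: float = 0.05
    output_cadence_days: float = 0.5
    # --- phase boundaries
    t_phase12: float = 1.5
    t_phase23: float = 4.0
    # --- zonation (cell-count distance from the attachment base)
    d_prolif: int = 4
    divisions_off_after_phase1: bool = False
    # --- cell division
    area_threshold_um2: float = 320.0
    apical_angle_deg: float = 60.0
    apical_period_days: float = 0.35
    apical_daughter_frac: float = 0.30
    # --- growth rates (per day)
    apical_k_par: float = 0.75
    apical_k_per: float = 0.40
    blade_k_par_phase1: float = 0.35
    blade_k_per_phase1: float = 0.30
    blade_k_par_phase2: float = 0.90
    blade_k_per_phase2: float = 0.38
    # basipetal gradient: blade rates attenuate linearly with cell-count
    # distance from the base, down to a floor fraction
    k_grad_slope: float = 0.15
    k_grad_floor: float = 0.25
    attach_k: float = 0.02
    # --- midrib
    midrib_t_onset: float = 2.0
    midrib_max_base_distance: int = 5
    midrib_max_offset_um: float = 9.0
    midrib_k_per_factor: float = 0.25
    # --- differentiation (transient elongation, then decay)
    diff_elongation_boost: float = 1.45
    diff_tau_e_days: float = 0.7
    diff_tau_d_days: float = 0.40
    # --- material / solver
    material_E_MPa: float = 100.0
    material_nu: float = 0.3
    solver_tol: float | None = 0.1
    solver_max_iter: int = 3000

    def __post_init__(self):
        if not (0 < self.t_phase12 < self.t_phase23):
            raise ValueError("require 0 < t_phase12 < t_phase23")
        if self.d_prolif < 1:
            raise ValueError("d_prolif must be >= 1")
        for name in ("dt_days", "diff_tau_e_days", "diff_tau_d_days",
                     "apical_period_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # ------------------------------------------------------------- io
    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @classmethod
    def for_scenario(cls, scenario: str) -> "ScenarioParams":
        """Load the shipped calibrated defaults for a named scenario."""
        if scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
        ref = resources.files("phyllidsim") / "params" / f"{scenario}.yaml"
        data = yaml.safe_load(ref.read_text())
        return cls(**data)
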