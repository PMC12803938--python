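"""Synthetic targeted-metabolomics data with known ground truth.

The generator emulates the statistical design of a two-genotype time-course
metabolomics experiment: two conditions × two timepoints (0 h and 20 h) ×
a few replicates, with positive, mean-unbiased multiplicative log-normal
replicate noise.  A :class:`Scenario` fixes true per-condition fold changes
(the 20 h / 0 h ratios), so parameter-recovery and end-to-end
differential-flux tests can compare pipeline output to an attached ground
truth computed on the bundled toy model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .analysis import FVASettings
from .differential import run_differential
from .metabolomics import AbundanceTable, MetaboliteMap, RatioTable
from .networks import PPP, build_toy_model, toy_metabolite_map

CONDITION_A = "flfl"
CONDITION_B = "r26"

#: plausible instrument-scale baseline intensities for the toy mapping
TOY_BASELINE_MEANS: Dict[str, float] = {
    "glucose": 1000.0,
    "glutamine": 400.0,
    "glycine": 300.0,
    "serine": 250.0,
    "arginine": 150.0,
    "lactate": 800.0,
    "alpha-ketoglutarate": 120.0,
}

#: metabolites whose late/early fold change feeds the PPP branch of the toy
#: model (glucose supplies glucose 6-phosphate, the oxidative-PPP substrate)
PPP_FEEDING_METABOLITES: Tuple[str, ...] = ("glucose",)


@dataclass
class Scenario:
    """A fully specified synthetic experiment.

    ``fold_changes`` maps (condition, metabolite) to the true 20 h / 0 h
    abundance ratio; ``noise_cv`` is the coefficient of variation of the
    multiplicative log-normal replicate noise (mean-unbiased).
    """

    metabolites: List[str]
    conditions: Tuple[str, str] = (CONDITION_A, CONDITION_B)
    n_replicates: int = 4
    baseline_means: Dict[str, float] = field(default_factory=dict)
    fold_changes: Dict[Tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.2
    seed: int = 0
    timepoints: Tuple[float, float] = (0.0, 20.0)
    expected_altered_reactions: Optional[List[str]] = None
    expected_decreased_reactions: Optional[List[str]] = None
    expected_decreased_ppp: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for key, fc in self.fold_changes.items():
            if fc <= 0:
                raise ValueError(f"fold change for {key} must be positive")
        for met in self.metabolites:
            if self.baseline_means.get(met, 1.0) <= 0:
                raise ValueError(f"baseline mean for {met!r} must be positive")

    def fold(self, condition: str, metabolite: str) -> float:
        return self.fold_changes.get((condition, metabolite), 1.0)

    def truth_dict(self) -> dict:
        return {
            "perturbed_metabolites": sorted(
                {m for (c, m), fc in self.fold_changes.items() if fc != 1.0}
            ),
            "expected_altered_reactions": self.expected_altered_reactions or [],
            "expected_decreased_reactions": self.expected_decreased_reactions or [],
            "expected_decreased_ppp": self.expected_decreased_ppp or [],
        }

    def write_truth(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.truth_dict(), indent=2, sort_keys=True) + "\n"
        )


def generate_abundance(scenario: Scenario) -> AbundanceTable:
    """Draw one synthetic abundance table from a scenario.

    Each sample abundance is ``baseline × fold × exp(ε)`` with the fold
    applied only at the late timepoint and ``ε ~ N(−σ²/2, σ²)``,
    ``σ² = ln(1 + cv²)``, so ``E[exp(ε)] = 1`` and the multiplicative CV
    equals ``noise_cv``.  Fully determined by ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    sigma2 = math.log1p(scenario.noise_cv**2)
    sigma = math.sqrt(sigma2)
    t_den, t_num = scenario.timepoints

    columns, meta_rows = [], []
    data: Dict[str, list] = {m: [] for m in scenario.metabolites}
    for condition in scenario.conditions:
        for timepoint in (t_den, t_num):
            for rep in range(1, scenario.n_replicates + 1):
                sample = f"{condition}_t{timepoint:g}_r{rep}"
                columns.append(sample)
                meta_rows.append(
                    {
                        "sample": sample,
                        "condition": condition,
                        "timepoint_h": timepoint,
                        "replicate": rep,
                    }
                )
                for met in scenario.metabolites:
                    mean = scenario.baseline_means.get(met, 1.0)
                    if timepoint == t_num:
                        mean *= scenario.fold(condition, met)
                    noise = (
                        math.exp(rng.normal(-sigma2 / 2.0, sigma))
                        if scenario.noise_cv > 0
                        else 1.0
                    )
                    data[met].append(mean * noise)

    values = pd.DataFrame(
        {s: [data[m][i] for m in scenario.metabolites] for i, s in enumerate(columns)},
        index=pd.Index(scenario.metabolites, name="metabolite"),
    )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return AbundanceTable(values=values, sample_meta=meta)


def exact_ratio_table(scenario: Scenario) -> RatioTable:
    """The noise-free ratio table implied by a scenario's fold changes."""
    t_den, t_num = scenario.timepoints
    rows = []
    for condition in scenario.conditions:
        for met in scenario.metabolites:
            base = scenario.baseline_means.get(met, 1.0)
            fold = scenario.fold(condition, met)
            rows.append(
                {
                    "condition": condition,
                    "metabolite": met,
                    "mean_den": base,
                    "mean_num": base * fold,
                    "n_den": scenario.n_replicates,
                    "n_num": scenario.n_replicates,
                    "ratio": fold,
                }
            )
    return RatioTable(data=pd.DataFrame(rows), t_num=t_num, t_den=t_den)


def knockdown_scenario(
    strength: float = 0.5,
    n_replicates: int = 4,
    noise_cv: float = 0.2,
    seed: int = 0,
    settings: Optional[FVASettings] = None,
    attach_ground_truth: bool = True,
) -> Scenario:
    """A toy-model scenario where one genotype loses PPP feed capacity.

    Condition ``flfl`` has all fold changes at 1.0; condition ``r26`` has
    the fold changes of the PPP-feeding metabolites multiplied by
    ``strength``.  With ``attach_ground_truth=True`` the scenario carries
    the altered/decreased reaction sets obtained by running the
    deterministic (noise-free) differential pipeline on the toy model,
    for use in recovery tests.
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    mapping = toy_metabolite_map()
    metabolites = list(mapping)
    fold_changes = {}
    for met in metabolites:
        fold_changes[(CONDITION_A, met)] = 1.0
        fold_changes[(CONDITION_B, met)] = (
            strength if met in PPP_FEEDING_METABOLITES else 1.0
        )
    scenario = Scenario(
        metabolites=metabolites,
        conditions=(CONDITION_A, CONDITION_B),
        n_replicates=n_replicates,
        baseline_means=dict(TOY_BASELINE_MEANS),
        fold_changes=fold_changes,
        noise_cv=noise_cv,
        seed=seed,
    )
    if attach_ground_truth:
        model = build_toy_model()
        report = run_differential(
            model,
            exact_ratio_table(scenario),
            MetaboliteMap(mapping),
            CONDITION_A,
            CONDITION_B,
            settings=settings or FVASettings(),
        )
        data = report.data
        scenario.expected_altered_reactions = sorted(data.index[data["altered"]])
        decreased = data.index[data["direction"] == "decreased"]
        scenario.expected_decreased_reactions = sorted(decreased)
        scenario.expected_decreased_ppp = sorted(
            data.index[(data["direction"] == "decreased") & (data["subsystem"] == PPP)]
        )
    return scenario
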