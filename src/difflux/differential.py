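"""Differential flux calling between two condition-parameterized models.

A reaction shows *altered flux* when its feasible flux range (from FVA)
differs between conditions in the lower or the upper bound, beyond a small
numerical tolerance.  On top of the binary call, each altered reaction is
classified directionally from the signed bound differences B − A:

- ``decreased``: the maximum dropped while the minimum did not drop,
- ``increased``: the mirror image,
- ``mixed``: anything else,
- ``unchanged``: not altered.

The entry point for end-to-end analyses is :class:`DifferentialFluxAnalysis`
(construct from a model + abundance data, call :meth:`~DifferentialFluxAnalysis.fit`,
inspect the returned :class:`DifferentialFluxResults`); the underlying staged
functions (:func:`compare_ranges`, :func:`run_differential`,
:func:`summarize_subsystems`) are public for pipeline use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import pandas as pd

from . import io as model_io
from .analysis import FVASettings, FluxDistribution, FluxRange, fba, fva, pfba
from .metabolomics import (
    AbundanceTable,
    MetaboliteMap,
    RatioTable,
    compute_ratios,
    ensure_exchanges,
    parameterize,
)
from .model import MetabolicModel

DIRECTIONS = ("unchanged", "decreased", "increased", "mixed")


def _different(a: float, b: float, abs_tol: float, rel_tol: float) -> bool:
    return abs(a - b) > max(abs_tol, rel_tol * max(abs(a), abs(b)))


@dataclass
class DifferentialFluxReport:
    """Per-reaction altered-flux calls between two conditions.

    ``data`` is indexed by reaction id with columns: subsystem, min_a,
    max_a, min_b, max_b, lower_changed, upper_changed, altered, direction.
    """

    data: pd.DataFrame
    condition_a: str
    condition_b: str
    settings: FVASettings = field(default_factory=FVASettings)
    abs_tol: float = 1e-6
    rel_tol: float = 1e-4

    @property
    def altered_ids(self) -> list:
        return list(self.data.index[self.data["altered"]])

    def directions(self) -> pd.Series:
        return self.data["direction"]

    def subsystem_summary(self) -> pd.DataFrame:
        return summarize_subsystems(self)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.data.rename_axis("reaction_id").to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "settings": self.settings.to_dict(),
            "tolerances": {"abs_tol": self.abs_tol, "rel_tol": self.rel_tol},
            "reactions": (
                self.data.rename_axis("reaction_id").reset_index().to_dict("records")
            ),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def compare_ranges(
    range_a: FluxRange,
    range_b: FluxRange,
    abs_tol: float = 1e-6,
    rel_tol: float = 1e-4,
    subsystems: Optional[Dict[str, str]] = None,
    condition_a: str = "A",
    condition_b: str = "B",
) -> DifferentialFluxReport:
    """Call altered flux per reaction from two FVA range sets.

    A bound pair (a, b) is *different* iff
    ``|a − b| > max(abs_tol, rel_tol · max(|a|, |b|))``.  Both inputs must
    cover the same reaction set.
    """
    ids_a, ids_b = set(range_a.ranges.index), set(range_b.ranges.index)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"reaction sets differ between conditions: {diff}")
    subsystems = subsystems or {}

    rows = []
    for rid in range_a.ranges.index:
        min_a, max_a = range_a[rid]
        min_b, max_b = range_b[rid]
        lower_changed = _different(min_a, min_b, abs_tol, rel_tol)
        upper_changed = _different(max_a, max_b, abs_tol, rel_tol)
        altered = lower_changed or upper_changed
        lower_down = lower_changed and min_b < min_a
        lower_up = lower_changed and min_b > min_a
        upper_down = upper_changed and max_b < max_a
        upper_up = upper_changed and max_b > max_a
        if not altered:
            direction = "unchanged"
        elif upper_down and not lower_down:
            direction = "decreased"
        elif upper_up and not lower_up:
            direction = "increased"
        else:
            direction = "mixed"
        rows.append(
            {
                "reaction_id": rid,
                "subsystem": subsystems.get(rid, ""),
                "min_a": min_a,
                "max_a": max_a,
                "min_b": min_b,
                "max_b": max_b,
                "lower_changed": lower_changed,
                "upper_changed": upper_changed,
                "altered": altered,
                "direction": direction,
            }
        )
    data = pd.DataFrame(rows).set_index("reaction_id")
    return DifferentialFluxReport(
        data=data,
        condition_a=condition_a,
        condition_b=condition_b,
        settings=range_a.settings,
        abs_tol=abs_tol,
        rel_tol=rel_tol,
    )


def summarize_subsystems(report: DifferentialFluxReport) -> pd.DataFrame:
    """Roll the per-reaction calls up to subsystem counts and fractions."""
    df = report.data
    rows = []
    for subsystem, grp in df.groupby("subsystem", sort=True):
        n = len(grp)
        n_altered = int(grp["altered"].sum())
        rows.append(
            {
                "subsystem": subsystem,
                "n_reactions": n,
                "n_altered": n_altered,
                "n_decreased": int((grp["direction"] == "decreased").sum()),
                "n_increased": int((grp["direction"] == "increased").sum()),
                "n_mixed": int((grp["direction"] == "mixed").sum()),
                "fraction_altered": n_altered / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("subsystem")


def run_differential(
    model: MetabolicModel,
    ratios: RatioTable,
    mapping: MetaboliteMap,
    condition_a: str,
    condition_b: str,
    settings: Optional[FVASettings] = None,
    abs_tol: float = 1e-6,
    rel_tol: float = 1e-4,
    zero_reference_policy: str = "leave",
    shared_optimum: bool = False,
) -> DifferentialFluxReport:
    """Full staged comparison: exchanges → reference pFBA → parameterize → FVA.

    By default each parameterized model is FVA-constrained by its own
    biomass optimum; ``shared_optimum=True`` constrains both by the base
    (pre-parameterization) model's optimum for sensitivity analysis.
    Deterministic for fixed inputs.
    """
    report, _ = _run_stages(
        model,
        ratios,
        mapping,
        condition_a,
        condition_b,
        settings=settings,
        abs_tol=abs_tol,
        rel_tol=rel_tol,
        zero_reference_policy=zero_reference_policy,
        shared_optimum=shared_optimum,
    )
    return report


def _run_stages(
    model: MetabolicModel,
    ratios: RatioTable,
    mapping: MetaboliteMap,
    condition_a: str,
    condition_b: str,
    settings: Optional[FVASettings] = None,
    abs_tol: float = 1e-6,
    rel_tol: float = 1e-4,
    zero_reference_policy: str = "leave",
    shared_optimum: bool = False,
):
    settings = settings or FVASettings()
    base = ensure_exchanges(model, mapping)
    reference = pfba(base, fraction_of_optimum=1.0)
    optimum = fba(base).objective_value if shared_optimum else None
    models = {}
    for condition in (condition_a, condition_b):
        models[condition] = parameterize(
            base,
            reference,
            ratios,
            condition,
            mapping,
            zero_reference_policy=zero_reference_policy,
        )
    range_a = fva(models[condition_a], settings, optimum=optimum)
    range_b = fva(models[condition_b], settings, optimum=optimum)
    subsystems = {r.id: r.subsystem for r in base.reactions}
    report = compare_ranges(
        range_a,
        range_b,
        abs_tol=abs_tol,
        rel_tol=rel_tol,
        subsystems=subsystems,
        condition_a=condition_a,
        condition_b=condition_b,
    )
    details = {
        "base": base,
        "reference": reference,
        "models": models,
        "ranges": {condition_a: range_a, condition_b: range_b},
    }
    return report, details


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------

class DifferentialFluxAnalysis:
    """Differential flux-capability analysis of two measured conditions.

    Couples a stoichiometric model with a targeted-metabolomics abundance
    table and a measured-name → model-metabolite mapping.  ``fit()`` runs
    the staged pipeline and returns a :class:`DifferentialFluxResults`.

    Parameters
    ----------
    model : MetabolicModel
        Base stoichiometric model with a biomass objective.
    abundance : AbundanceTable
        Measurements for two conditions at two timepoints.
    mapping : MetaboliteMap
        Explicit measured-name → model-metabolite-id map.
    condition_a, condition_b : str
        Labels of the conditions to compare (report direction is B − A).
    t_num, t_den : float
        Timepoints (hours) for the abundance ratio, late over early.
    """

    def __init__(
        self,
        model: MetabolicModel,
        abundance: AbundanceTable,
        mapping: MetaboliteMap,
        condition_a: str,
        condition_b: str,
        t_num: float = 20.0,
        t_den: float = 0.0,
        settings: Optional[FVASettings] = None,
        abs_tol: float = 1e-6,
        rel_tol: float = 1e-4,
        zero_reference_policy: str = "leave",
        shared_optimum: bool = False,
    ) -> None:
        self.model = model
        self.abundance = abundance
        self.mapping = mapping
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.t_num = t_num
        self.t_den = t_den
        self.settings = settings or FVASettings()
        self.abs_tol = abs_tol
        self.rel_tol = rel_tol
        self.zero_reference_policy = zero_reference_policy
        self.shared_optimum = shared_optimum

    @classmethod
    def from_files(
        cls,
        model_path: Union[str, Path],
        abundance_path: Union[str, Path],
        metadata_path: Union[str, Path],
        mapping_path: Union[str, Path],
        condition_a: str,
        condition_b: str,
        model_format: str = "json",
        **kwargs,
    ) -> "DifferentialFluxAnalysis":
        return cls(
            model=model_io.read_model(model_path, format=model_format),
            abundance=AbundanceTable.from_tsv(abundance_path, metadata_path),
            mapping=MetaboliteMap.from_tsv(mapping_path),
            condition_a=condition_a,
            condition_b=condition_b,
            **kwargs,
        )

    def fit(self) -> "DifferentialFluxResults":
        ratios = compute_ratios(self.abundance, t_num=self.t_num, t_den=self.t_den)
        report, details = _run_stages(
            self.model,
            ratios,
            self.mapping,
            self.condition_a,
            self.condition_b,
            settings=self.settings,
            abs_tol=self.abs_tol,
            rel_tol=self.rel_tol,
            zero_reference_policy=self.zero_reference_policy,
            shared_optimum=self.shared_optimum,
        )
        return DifferentialFluxResults(
            analysis=self,
            report=report,
            ratios=ratios,
            reference=details["reference"],
        )


class DifferentialFluxResults:
    """Fitted differential-flux results: calls, rollups and provenance."""

    def __init__(
        self,
        analysis: DifferentialFluxAnalysis,
        report: DifferentialFluxReport,
        ratios: RatioTable,
        reference: FluxDistribution,
    ) -> None:
        self.analysis = analysis
        self.report = report
        self.ratios = ratios
        self.reference = reference

    @property
    def per_reaction(self) -> pd.DataFrame:
        return self.report.data

    @property
    def subsystem_summary(self) -> pd.DataFrame:
        return self.report.subsystem_summary()

    @property
    def n_altered(self) -> int:
        return int(self.report.data["altered"].sum())

    def summary(self) -> str:
        """Human-readable summary table, statsmodels-style."""
        rep = self.report
        head = [
            "Differential Flux Variability Results",
            "=" * 64,
            f"conditions:        {rep.condition_a} (A) vs {rep.condition_b} (B)",
            f"reactions:         {len(rep.data)}",
            f"altered:           {self.n_altered}",
            f"fraction_of_optimum={rep.settings.fraction_of_optimum}  "
            f"pfba_factor={rep.settings.pfba_factor}  "
            f"loopless={rep.settings.loopless}",
            f"tolerances:        abs={rep.abs_tol}  rel={rep.rel_tol}",
            "-" * 64,
        ]
        summ = self.subsystem_summary.reset_index()
        body = summ.to_string(
            index=False,
            float_format=lambda x: f"{x:.3f}",
        ).splitlines()
        return "\n".join(head + body + ["=" * 64])

    def save(self, outdir: Union[str, Path]) -> Dict[str, Path]:
        """Write report.tsv, summary.tsv, report.json into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": outdir / "report.tsv",
            "summary": outdir / "summary.tsv",
            "json": outdir / "report.json",
        }
        self.report.to_tsv(paths["report"])
        self.subsystem_summary.to_csv(paths["summary"], sep="\t")
        self.report.to_json(paths["json"])
        return paths
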