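"""Metabolomics integration: abundance tables, ratios, model parameterization.

The pipeline step implemented here turns targeted-metabolomics measurements
into condition-specific models: per-condition late/early abundance ratios are
computed from replicate means, every measured metabolite is guaranteed an
exchange reaction (artificial ones are added where the model lacks them), and
exchange bounds are rescaled by reference-flux × ratio so each condition's
model reflects its demonstrated consumption/secretion capacity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .analysis import FluxDistribution
from .model import MetabolicModel, Reaction

logger = logging.getLogger(__name__)

ZERO_REFERENCE_POLICIES = ("leave", "clamp", "epsilon")


# ---------------------------------------------------------------------------
# abundance data
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Metabolite × sample abundances with per-sample condition/timepoint.

    ``values``: DataFrame, rows = metabolites, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``condition``, ``timepoint_h``, ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("condition", "timepoint_h", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("abundances must be finite")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def metabolites(self) -> List[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> List[str]:
        return sorted(self.sample_meta["condition"].unique())

    def samples_for(self, condition: str, timepoint: float) -> List[str]:
        meta = self.sample_meta
        mask = (meta["condition"] == condition) & (meta["timepoint_h"] == timepoint)
        return [s for s in meta.index[mask] if s in self.values.columns]

    @classmethod
    def from_tsv(
        cls, values_path: Union[str, Path], meta_path: Union[str, Path]
    ) -> "AbundanceTable":
        sep_v = "," if str(values_path).endswith(".csv") else "\t"
        sep_m = "," if str(meta_path).endswith(".csv") else "\t"
        values = pd.read_csv(values_path, sep=sep_v, index_col=0)
        meta = pd.read_csv(meta_path, sep=sep_m, index_col=0)
        return cls(values=values, sample_meta=meta)

    def to_tsv(
        self, values_path: Union[str, Path], meta_path: Union[str, Path]
    ) -> None:
        self.values.rename_axis("metabolite").to_csv(values_path, sep="\t")
        self.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


@dataclass
class RatioTable:
    """Per-(condition, metabolite) abundance ratios with provenance.

    ``data`` columns: condition, metabolite, mean_den, mean_num, n_den,
    n_num, ratio.  ``dropped`` lists (condition, metabolite, reason) entries
    excluded for nonpositive denominator means.
    """

    data: pd.DataFrame
    t_num: float = 20.0
    t_den: float = 0.0
    dropped: List[Tuple[str, str, str]] = field(default_factory=list)

    @property
    def conditions(self) -> List[str]:
        return sorted(self.data["condition"].unique())

    def has_condition(self, condition: str) -> bool:
        return condition in set(self.data["condition"])

    def ratio(self, condition: str, metabolite: str) -> Optional[float]:
        sel = self.data[
            (self.data["condition"] == condition)
            & (self.data["metabolite"] == metabolite)
        ]
        if sel.empty:
            return None
        return float(sel["ratio"].iloc[0])

    def to_tsv(self, path: Union[str, Path]) -> None:
        def _fmt(t: float) -> str:
            return str(int(t)) if float(t).is_integer() else str(t)

        out = self.data.rename(
            columns={
                "mean_den": f"mean_t{_fmt(self.t_den)}",
                "mean_num": f"mean_t{_fmt(self.t_num)}",
                "n_den": f"n_t{_fmt(self.t_den)}",
                "n_num": f"n_t{_fmt(self.t_num)}",
            }
        )
        out.to_csv(path, sep="\t", index=False)


def compute_ratios(
    table: AbundanceTable,
    t_num: float = 20.0,
    t_den: float = 0.0,
    ratio_min: Optional[float] = None,
    ratio_max: Optional[float] = None,
) -> RatioTable:
    """Per-condition ratio of replicate-mean abundances, t_num over t_den.

    Metabolites whose denominator mean is nonpositive are dropped with a
    logged warning and recorded in ``RatioTable.dropped``.  ``ratio_min`` /
    ``ratio_max`` optionally truncate extreme ratios (default: pass-through).
    """
    if table.values.empty:
        raise ValueError("abundance table is empty")
    rows = []
    dropped: List[Tuple[str, str, str]] = []
    for condition in table.conditions:
        num_samples = table.samples_for(condition, t_num)
        den_samples = table.samples_for(condition, t_den)
        if not num_samples or not den_samples:
            raise ValueError(
                f"condition {condition!r} lacks samples at timepoint "
                f"{t_num if not num_samples else t_den}"
            )
        for met in table.metabolites:
            mean_num = float(table.values.loc[met, num_samples].mean())
            mean_den = float(table.values.loc[met, den_samples].mean())
            if mean_den <= 0:
                reason = f"nonpositive denominator mean ({mean_den})"
                dropped.append((condition, met, reason))
                logger.warning(
                    "dropping metabolite %r in condition %r: %s",
                    met,
                    condition,
                    reason,
                )
                continue
            ratio = mean_num / mean_den
            if ratio_min is not None:
                ratio = max(ratio, ratio_min)
            if ratio_max is not None:
                ratio = min(ratio, ratio_max)
            rows.append(
                {
                    "condition": condition,
                    "metabolite": met,
                    "mean_den": mean_den,
                    "mean_num": mean_num,
                    "n_den": len(den_samples),
                    "n_num": len(num_samples),
                    "ratio": ratio,
                }
            )
    data = pd.DataFrame(
        rows,
        columns=[
            "condition",
            "metabolite",
            "mean_den",
            "mean_num",
            "n_den",
            "n_num",
            "ratio",
        ],
    )
    return RatioTable(data=data, t_num=t_num, t_den=t_den, dropped=dropped)


# ---------------------------------------------------------------------------
# metabolite → model mapping
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteMap:
    """Explicit measured-name → model-metabolite-id mapping (no fuzzy match)."""

    entries: Dict[str, str]

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "MetaboliteMap":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(
                f"{path}: mapping needs two columns "
                "(measured_name, model_metabolite_id)"
            )
        col_name, col_target = df.columns[:2]
        return cls(entries=dict(zip(df[col_name].astype(str), df[col_target].astype(str))))

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            sorted(self.entries.items()),
            columns=["measured_name", "model_metabolite_id"],
        ).to_csv(path, sep="\t", index=False)

    def validate_against(self, model: MetabolicModel) -> None:
        met_ids = set(model.metabolite_ids)
        missing = sorted(set(self.entries.values()) - met_ids)
        if missing:
            raise ValueError(
                f"mapped metabolites absent from model {model.id!r}: {missing}"
            )


# ---------------------------------------------------------------------------
# model parameterization
# ---------------------------------------------------------------------------

def synthetic_exchange_id(metabolite_id: str) -> str:
    return f"EX_{metabolite_id}_synthetic"


def ensure_exchanges(model: MetabolicModel, mapping: MetaboliteMap) -> MetabolicModel:
    """Return a copy where every mapped metabolite has an exchange reaction.

    Added reactions are flagged artificial, get bounds
    (−default_bound, +default_bound), subsystem "Exchange" and the id
    ``EX_<metabolite-id>_synthetic``.  Calling twice is a no-op.
    """
    mapping.validate_against(model)
    out = model.copy()
    added = []
    for mid in dict.fromkeys(mapping.entries.values()):  # preserve order, dedupe
        if out.exchanges_for(mid):
            continue
        rid = synthetic_exchange_id(mid)
        out.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={mid: -1.0},
                lower_bound=-out.default_bound,
                upper_bound=out.default_bound,
                subsystem="Exchange",
                is_exchange=True,
                is_artificial=True,
            )
        )
        added.append(rid)
    if added:
        logger.info("added artificial exchanges: %s", added)
    out.notes.setdefault("artificial_exchanges", []).extend(added)
    return out


def parameterize(
    model: MetabolicModel,
    reference: FluxDistribution,
    ratios: RatioTable,
    condition: str,
    mapping: MetaboliteMap,
    zero_reference_policy: str = "leave",
    zero_tolerance: float = 1e-9,
) -> MetabolicModel:
    """Scale exchange bounds of measured metabolites by reference × ratio.

    For each mapped metabolite with exchange flux ``v*`` in the reference
    distribution, the new capacity is ``b = v* × ratio(condition, m)``: an
    uptake reference (``v* < 0``) resets the lower bound, a secretion
    reference (``v* > 0``) the upper bound; the opposite bound is untouched
    so the exchange keeps its direction repertoire.  Zero-reference
    exchanges follow ``zero_reference_policy``:

    - ``leave`` (default): bounds unchanged, metabolite logged;
    - ``clamp``: exchange fixed to zero flux;
    - ``epsilon``: bounds set to ±1e-6 × default_bound.

    The decisions taken are recorded in ``model.notes["parameterization"]``.
    """
    if zero_reference_policy not in ZERO_REFERENCE_POLICIES:
        raise ValueError(
            f"zero_reference_policy must be one of {ZERO_REFERENCE_POLICIES}"
        )
    if not ratios.has_condition(condition):
        raise ValueError(
            f"condition {condition!r} absent from ratio table "
            f"(has {ratios.conditions})"
        )
    out = model.copy()
    provenance: Dict = {
        "condition": condition,
        "zero_reference": [],
        "unmeasured": [],
        "scaled": {},
    }
    eps = 1e-6 * out.default_bound
    for name, mid in mapping.entries.items():
        ratio = ratios.ratio(condition, name)
        if ratio is None:
            provenance["unmeasured"].append(name)
            continue
        for exchange in out.exchanges_for(mid):
            rid = exchange.id
            if rid not in reference.fluxes.index:
                raise ValueError(
                    f"reference distribution lacks exchange {rid!r}; it must "
                    "be computed on the post-ensure_exchanges model"
                )
            v_star = float(reference.fluxes[rid])
            if abs(v_star) <= zero_tolerance:
                provenance["zero_reference"].append(name)
                if zero_reference_policy == "clamp":
                    exchange.lower_bound = 0.0
                    exchange.upper_bound = 0.0
                elif zero_reference_policy == "epsilon":
                    exchange.lower_bound = -eps
                    exchange.upper_bound = eps
                continue
            b = v_star * ratio
            if v_star < 0:
                exchange.lower_bound = b
                side = "lower"
            else:
                exchange.upper_bound = b
                side = "upper"
            provenance["scaled"][rid] = {
                "metabolite": name,
                "reference_flux": v_star,
                "ratio": ratio,
                "new_bound": b,
                "side": side,
            }
    out.notes["parameterization"] = provenance
    out.id = f"{model.id}_{condition}"
    return out
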