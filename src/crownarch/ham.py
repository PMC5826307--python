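"""Hallé architecture model (HAM) identification and growth-habit retrieval.

Hallé's scheme condenses tree trunk/branch organization and growth rhythm
into qualitative archetypes; four of them cover the common boreal species:
Massart (plagiotropic whorled branches, rhythmic growth), Rauh (orthotropic
branches equivalent to the trunk, rhythmic), Roux (plagiotropic monopodial,
continuous) and Attim (orthotropic, more or less continuous).

Identification is per *species*, not per tree: after classification, the
centre of a species' distribution over a feature pair (default P4-P7) is
compared with packaged prototype centres.  The default rule assigns the
nearest prototype after per-axis min-max scaling over the prototypes; a
quadrant rule with user cut lines is available for feature pairs with a
genuine 2x2 layout.  A Gaussian mu/sigma summary quantifies how much the
classification shifted per-species feature distributions relative to the
true labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HAMModel",
    "HAMKnowledge",
    "HAMAssignment",
    "load_knowledge",
    "species_center",
    "assign_ham",
    "habits_for",
    "gaussian_summary",
]


@dataclass(frozen=True)
class HAMModel:
    """One architecture model: habit texts plus a prototype feature-pair centre."""

    name: str
    trunk: str
    branches: str
    growth: str
    center: tuple[float, float]
    quadrant: tuple[str, str]


@dataclass(frozen=True)
class HAMKnowledge:
    """The packaged model set with its feature pair and quadrant map."""

    feature_pair: tuple[str, str]
    models: dict[str, HAMModel]
    quadrant_map: dict[tuple[str, str], str]
    species_links: dict[str, dict[str, str]]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.models)

    def centers(self) -> np.ndarray:
        return np.array([m.center for m in self.models.values()], dtype=float)


@dataclass(frozen=True)
class HAMAssignment:
    """Assignment of one species (or centre) to an architecture model."""

    species: str | None
    assigned: str
    center: tuple[float, float]
    margin: float  # scaled-distance gap to the second-best prototype
    rule: str


def load_knowledge(path: str | Path | None = None) -> HAMKnowledge:
    """Load the HAM knowledge base (packaged YAML by default)."""
    if path is None:
        text = resources.files("crownarch.data").joinpath("ham_knowledge.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    pair = tuple(raw["feature_pair"])
    models: dict[str, HAMModel] = {}
    for name, spec in raw["models"].items():
        center = tuple(float(spec["center"][f]) for f in pair)
        models[name] = HAMModel(
            name=name,
            trunk=spec["trunk"],
            branches=spec["branches"],
            growth=spec["growth"],
            center=center,
            quadrant=tuple(spec["quadrant"]),
        )
    centers = np.array([m.center for m in models.values()])
    if len(models) != len({tuple(c) for c in centers.round(12).tolist()}):
        raise ValueError("prototype centres must be pairwise distinct")
    qmap = {tuple(k.split(",")): v for k, v in raw.get("quadrant_map", {}).items()}
    return HAMKnowledge(
        feature_pair=pair,
        models=models,
        quadrant_map=qmap,
        species_links=raw.get("species_links", {}),
    )


def species_center(
    table: pd.DataFrame,
    species: str,
    pair: tuple[str, str],
    scope: str = "all_assigned",
    predictions: pd.Series | None = None,
) -> tuple[float, float]:
    """Arithmetic mean of a feature pair over one species' trees.

    ``scope='all_assigned'`` averages every tree predicted as ``species``
    (falling back to the true labels when no predictions are given);
    ``scope='correct_only'`` restricts to correctly classified trees.
    """
    if scope not in ("all_assigned", "correct_only"):
        raise ValueError(f"unknown scope {scope!r}")
    labels = (
        predictions.reindex(table["tree_id"]).to_numpy()
        if predictions is not None
        else table["species"].to_numpy()
    )
    mask = labels == species
    if scope == "correct_only":
        mask &= table["species"].to_numpy() == species
    sub = table.loc[mask, list(pair)]
    if len(sub) == 0:
        raise ValueError(f"no trees in scope for species {species!r}")
    f1, f2 = sub.mean(axis=0)
    return float(f1), float(f2)


def _minmax_scale(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    lo = ref.min(axis=0)
    span = ref.max(axis=0) - lo
    span = np.where(span < 1e-12, 1.0, span)
    return (values - lo) / span


def assign_ham(
    center: tuple[float, float],
    knowledge: HAMKnowledge,
    rule: str = "nearest_center",
    species: str | None = None,
    thresholds: tuple[float, float] | None = None,
    quadrant_map: dict[tuple[str, str], str] | None = None,
) -> HAMAssignment:
    """Assign the architecture model for a species feature-pair centre.

    ``nearest_center`` (default): minimal Euclidean distance to a prototype
    after per-axis min-max scaling over the prototypes (hence invariant to
    affine rescaling of either axis).  ``quadrant``: the sign pattern of
    ``(f1 - t1, f2 - t2)`` against configured cut lines, mapped through the
    quadrant->model table; values exactly on a cut line tie-break to the
    lower quadrant with a warning.
    """
    c = np.asarray(center, dtype=float)
    protos = knowledge.centers()
    names = list(knowledge.names)
    if rule == "nearest_center":
        scaled_p = _minmax_scale(protos, protos)
        scaled_c = _minmax_scale(c, protos)
        dists = np.linalg.norm(scaled_p - scaled_c, axis=1)
        order = np.argsort(dists, kind="stable")
        assigned = names[order[0]]
        margin = float(dists[order[1]] - dists[order[0]]) if len(names) > 1 else float("inf")
    elif rule == "quadrant":
        if thresholds is None:
            raise ValueError("quadrant rule requires thresholds=(t1, t2)")
        qmap = quadrant_map or knowledge.quadrant_map
        codes = []
        for v, t in zip(c, thresholds):
            if v == t:
                warnings.warn(
                    f"centre value {v} exactly on cut line {t}; tie-break to lower quadrant"
                )
            codes.append("low" if v <= t else "high")
        key = tuple(codes)
        if key not in qmap:
            raise ValueError(f"quadrant {key} not mapped to any model")
        assigned = qmap[key]
        margin = float(min(abs(v - t) for v, t in zip(c, thresholds)))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if assigned not in knowledge.models:
        raise ValueError(f"assigned model {assigned!r} not in knowledge base")
    return HAMAssignment(
        species=species,
        assigned=assigned,
        center=(float(c[0]), float(c[1])),
        margin=margin,
        rule=rule,
    )


def habits_for(ham: str, knowledge: HAMKnowledge) -> dict[str, str]:
    """Trunk / branches / growth habit texts for a model name."""
    if ham not in knowledge.models:
        raise ValueError(
            f"unknown architecture model {ham!r}; valid names: {sorted(knowledge.names)}"
        )
    m = knowledge.models[ham]
    return {"model": m.name, "trunk": m.trunk, "branches": m.branches, "growth": m.growth}


def gaussian_summary(
    table: pd.DataFrame,
    predictions: pd.Series,
    parameters: list[str],
) -> pd.DataFrame:
    """Gaussian mu/sigma per species x parameter, predicted vs true labels.

    For each species and parameter the Gaussian maximum-likelihood fit
    (mu = mean, sigma = population sd) is computed on the predicted-label
    group (DP) and the true-label group (GT), with the relative divergences
    ``delta_mu_pct = (mu_GT - mu_DP) / mu_GT * 100`` and analogously for
    sigma.  Groups of size < 2 report sigma 0 with a warning.
    """
    pred = predictions.reindex(table["tree_id"])
    if pred.isna().any():
        missing = table.loc[pred.isna().to_numpy(), "tree_id"].tolist()
        raise ValueError(f"predictions missing for trees {missing}")
    pred = pred.to_numpy()
    truth = table["species"].to_numpy()
    rows = []
    for sp in sorted(np.unique(truth)):
        for par in parameters:
            vals = table[par].to_numpy(dtype=float)
            stats = {}
            for tag, mask in (("dp", pred == sp), ("gt", truth == sp)):
                group = vals[mask]
                if len(group) == 0:
                    warnings.warn(f"gaussian_summary: no {tag.upper()} trees for {sp!r}")
                    stats[tag] = (float("nan"), float("nan"))
                    continue
                if len(group) < 2:
                    warnings.warn(
                        f"gaussian_summary: {tag.upper()} group for {sp!r} has <2 trees; sigma=0"
                    )
                stats[tag] = (float(group.mean()),
                              float(group.std()) if len(group) > 1 else 0.0)
            mu_dp, sd_dp = stats["dp"]
            mu_gt, sd_gt = stats["gt"]
            rows.append(
                {
                    "species": sp,
                    "parameter": par,
                    "mu_dp": mu_dp,
                    "sigma_dp": sd_dp,
                    "mu_gt": mu_gt,
                    "sigma_gt": sd_gt,
                    "delta_mu_pct": (mu_gt - mu_dp) / mu_gt * 100 if mu_gt else float("nan"),
                    "delta_sigma_pct": (sd_gt - sd_dp) / sd_gt * 100 if sd_gt else float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index(["species", "parameter"])
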