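"""Reading and writing of the package's on-disk artifacts.

On-disk response categories are 1..K+1 (matching the seven-point Likert
presentation); in memory they are 0..K.  The conversion happens here and only
here.  Model parameters round-trip through JSON; responses, weight tables, and
rating histograms through CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .desirability import RatingHistogram
from .estimate import FitResult
from .model import (
    MISSING,
    Dimension,
    ItemParameters,
    LatentDistribution,
    ModelSpec,
    PersonParameters,
    ResponseMatrix,
)

__all__ = [
    "write_responses_csv",
    "read_responses_csv",
    "spec_to_dict",
    "spec_from_dict",
    "write_model_json",
    "read_model_json",
    "write_fit_json",
    "read_fit_json",
    "write_weights_csv",
    "read_weights_csv",
    "write_ratings_csv",
    "read_ratings_csv",
    "write_theta_csv",
]

PathLike = Union[str, Path]


def write_responses_csv(path: PathLike, responses: ResponseMatrix) -> None:
    """One row per person, header of item ids, categories stored as 1..K+1."""
    vals = responses.values.copy()
    observed = vals != MISSING
    out = np.where(observed, vals + 1, np.nan).astype(object)
    df = pd.DataFrame(out, columns=responses.item_ids, index=responses.person_ids)
    df.index.name = "person_id"
    df.to_csv(path)


def read_responses_csv(path: PathLike) -> ResponseMatrix:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    out = np.where(np.isnan(vals), MISSING, np.nan_to_num(vals) - 1).astype(np.int64)
    return ResponseMatrix(
        values=out,
        item_ids=[str(c) for c in df.columns],
        person_ids=[str(i) for i in df.index],
    )


def spec_to_dict(spec: ModelSpec) -> Dict:
    return {
        "n_categories": spec.n_categories,
        "dimensions": [{"label": d.label, "role": d.role} for d in spec.dimensions],
        "item_ids": list(spec.item_ids),
        "item_trait": dict(spec.item_trait),
    }


def spec_from_dict(data: Dict) -> ModelSpec:
    return ModelSpec(
        n_categories=int(data["n_categories"]),
        dimensions=[Dimension(d["label"], d["role"]) for d in data["dimensions"]],
        item_ids=list(data["item_ids"]),
        item_trait=dict(data["item_trait"]),
    )


def _items_to_list(items: Sequence[ItemParameters]) -> List[Dict]:
    return [
        {
            "item_id": it.item_id,
            "slopes": it.slopes.tolist(),
            "intercepts": it.intercepts.tolist(),
            "scoring_weights": it.scoring_weights.tolist(),
        }
        for it in items
    ]


def _items_from_list(data: Sequence[Dict]) -> List[ItemParameters]:
    return [
        ItemParameters(
            slopes=np.asarray(d["slopes"]),
            intercepts=np.asarray(d["intercepts"]),
            scoring_weights=np.asarray(d["scoring_weights"]),
            item_id=d.get("item_id", ""),
        )
        for d in data
    ]


def write_model_json(
    path: PathLike,
    spec: ModelSpec,
    items: Sequence[ItemParameters],
    latent: LatentDistribution,
) -> None:
    payload = {
        "spec": spec_to_dict(spec),
        "items": _items_to_list(items),
        "latent": {
            "mean": latent.mean.tolist(),
            "covariance": latent.covariance.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_json(path: PathLike):
    data = json.loads(Path(path).read_text())
    spec = spec_from_dict(data["spec"])
    items = _items_from_list(data["items"])
    latent = LatentDistribution(
        mean=np.asarray(data["latent"]["mean"]),
        covariance=np.asarray(data["latent"]["covariance"]),
    )
    return spec, items, latent


def write_fit_json(path: PathLike, fit: FitResult) -> None:
    payload = {
        "spec": spec_to_dict(fit.spec),
        "items": _items_to_list(fit.items),
        "sigma": fit.sigma.tolist(),
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "n_cycles": fit.n_cycles,
        "algorithm": fit.algorithm,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_json(path: PathLike) -> FitResult:
    data = json.loads(Path(path).read_text())
    return FitResult(
        spec=spec_from_dict(data["spec"]),
        items=_items_from_list(data["items"]),
        sigma=np.asarray(data["sigma"]),
        loglik=float(data["loglik"]),
        n_params=int(data["n_params"]),
        n_obs=int(data["n_obs"]),
        converged=bool(data["converged"]),
        n_cycles=int(data["n_cycles"]),
        algorithm=str(data["algorithm"]),
    )


def write_weights_csv(path: PathLike, rows: Dict[str, Dict[str, np.ndarray]]) -> None:
    """Weight table: one row per (item, dimension) with K+1 weight columns."""
    records = []
    for item_id, dims in rows.items():
        for dim, w in dims.items():
            rec = {"item_id": item_id, "dimension": dim}
            rec.update({f"w{k}": float(v) for k, v in enumerate(np.asarray(w))})
            records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_weights_csv(path: PathLike) -> Dict[str, Dict[str, np.ndarray]]:
    df = pd.read_csv(path)
    wcols = sorted([c for c in df.columns if c.startswith("w")], key=lambda c: int(c[1:]))
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["item_id"]), {})[str(row["dimension"])] = np.asarray(
            [row[c] for c in wcols], dtype=float
        )
    return out


def write_ratings_csv(path: PathLike, histograms: Sequence[RatingHistogram]) -> None:
    """Rating histograms: counts per on-disk category c1..c(K+1)."""
    records = []
    for h in histograms:
        rec = {"item_id": h.item_id, "keying": h.keying}
        rec.update({f"c{k + 1}": int(c) for k, c in enumerate(h.counts)})
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def read_ratings_csv(path: PathLike) -> List[RatingHistogram]:
    df = pd.read_csv(path)
    ccols = sorted([c for c in df.columns if c.startswith("c")], key=lambda c: int(c[1:]))
    return [
        RatingHistogram(
            item_id=str(row["item_id"]),
            counts=tuple(int(row[c]) for c in ccols),
            keying=str(row["keying"]),
        )
        for _, row in df.iterrows()
    ]


def write_theta_csv(path: PathLike, persons: PersonParameters, labels: Sequence[str]) -> None:
    df = pd.DataFrame(persons.values, columns=list(labels))
    df.index.name = "person"
    df.to_csv(path)
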