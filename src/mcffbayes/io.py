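"""Readers and writers for trial tables, posterior draws, and truth bundles.

Everything is plain text: trial data as CSV (see :mod:`mcffbayes.data`),
posterior draws as a labelled columnar CSV (one row per chain x sample)
with a JSON sidecar carrying provenance (model tag, K, subject/test pairs,
convergence ratios, seed), and simulation ground truth as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import TrialDataset
from .inference import PosteriorSamples, SamplerConfig
from .model import SessionStructure
from .simulate import TruthBundle

__all__ = [
    "read_trials",
    "write_trials",
    "write_posterior",
    "read_posterior",
    "write_truth",
    "read_truth",
    "load_sampler_config",
    "PosteriorSchemaError",
]


class PosteriorSchemaError(ValueError):
    """Stored posterior does not match the expected model/schema."""


def read_trials(path: str | Path) -> TrialDataset:
    """Load and validate a trial-table CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return TrialDataset.read_csv(path)


def write_trials(dataset: TrialDataset, path: str | Path) -> None:
    dataset.to_csv(path)


def _paths(prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    return prefix.with_suffix(".csv"), prefix.with_suffix(".meta.json")


def write_posterior(post: PosteriorSamples, prefix: str | Path) -> None:
    """Write draws to ``<prefix>.csv`` and metadata to ``<prefix>.meta.json``."""
    csv_path, meta_path = _paths(prefix)
    post.to_dataframe().to_csv(csv_path, index=False)
    meta = {
        "model": post.model,
        "K": post.K,
        "names": list(post.names),
        "pairs": [list(p) for p in post.pairs],
        "rhat": [float(r) for r in post.rhat],
        "converged": bool(post.converged),
        "beta_fixed": post.beta_fixed,
        "seed": post.seed,
        "n_chains": post.n_chains,
        "n_kept": post.n_kept,
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_posterior(
    prefix: str | Path, expect_model: str | None = None
) -> PosteriorSamples:
    """Lossless counterpart of :func:`write_posterior`.

    ``expect_model`` guards against loading draws from a different
    procedure (raises :class:`PosteriorSchemaError` on mismatch).
    """
    csv_path, meta_path = _paths(prefix)
    meta = json.loads(meta_path.read_text())
    if expect_model is not None and meta["model"] != expect_model:
        raise PosteriorSchemaError(
            f"stored posterior is from model {meta['model']!r}, expected {expect_model!r}"
        )
    df = pd.read_csv(csv_path, float_precision="round_trip")
    names = meta["names"]
    missing = [n for n in names if n not in df.columns]
    if missing or "chain" not in df.columns or "draw" not in df.columns:
        raise PosteriorSchemaError(f"posterior table missing columns: {missing[:5]}")
    nc, ns = int(meta["n_chains"]), int(meta["n_kept"])
    draws = (
        df.sort_values(["chain", "draw"])[names]
        .to_numpy()
        .reshape(nc, ns, len(names))
    )
    return PosteriorSamples(
        model=meta["model"],
        K=int(meta["K"]),
        names=tuple(names),
        draws=draws,
        pairs=tuple((int(s), int(j)) for s, j in meta["pairs"]),
        rhat=np.array(meta["rhat"]),
        converged=bool(meta["converged"]),
        beta_fixed=meta["beta_fixed"],
        seed=int(meta["seed"]),
    )


def write_truth(truth: TruthBundle, path: str | Path, include_curves: bool = True) -> None:
    """Serialize a simulation's latent ground truth as JSON."""
    spec = truth.spec
    payload = {
        "spec": {
            "K": spec.K,
            "mu": np.asarray(spec.mu).tolist(),
            "Sigma": np.asarray(spec.Sigma).tolist(),
            "phi_cov": np.asarray(spec.phi_cov).tolist(),
            "beta": spec.beta,
            "n_sessions": spec.n_sessions,
            "trials_per_session": spec.trials_per_session,
            "n_tests": spec.n_tests,
            "pretrain_range": list(spec.pretrain_range),
        },
        "group_of": {str(s): g for s, g in truth.group_of.items()},
        "rho": {str(s): v.tolist() for s, v in truth.rho.items()},
        "theta": {f"{s},{j}": v.tolist() for (s, j), v in truth.theta.items()},
        "structures": {
            str(s): {
                "n_sessions": st.n_sessions,
                "trials_per_session": list(st._tps()),
                "pretrain_trials": st.pretrain_trials,
            }
            for s, st in truth.structures.items()
        },
    }
    if include_curves:
        payload["curves"] = {
            f"{s},{j}": np.round(v, 6).tolist() for (s, j), v in truth.curves.items()
        }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> dict:
    """Load a truth-bundle JSON back as a dict of arrays."""
    payload = json.loads(Path(path).read_text())
    out = {
        "spec": payload["spec"],
        "group_of": {int(s): g for s, g in payload["group_of"].items()},
        "rho": {int(s): np.array(v) for s, v in payload["rho"].items()},
        "theta": {
            tuple(int(x) for x in k.split(",")): np.array(v)
            for k, v in payload["theta"].items()
        },
        "structures": {
            int(s): SessionStructure(
                n_sessions=d["n_sessions"],
                trials_per_session=d["trials_per_session"],
                pretrain_trials=d["pretrain_trials"],
            )
            for s, d in payload["structures"].items()
        },
    }
    if "curves" in payload:
        out["curves"] = {
            tuple(int(x) for x in k.split(",")): np.array(v)
            for k, v in payload["curves"].items()
        }
    return out


def load_sampler_config(path: str | Path, seed: int | None = None) -> SamplerConfig:
    """Build a :class:`SamplerConfig` from a flat key-value YAML file.

    Recognised keys are the dataclass fields (``n_chains``, ``kept``,
    ``thin``, ``burn_in``, ``adaptation``, ``rhat_threshold``, ``seed``);
    unknown keys raise.  ``seed`` given here overrides the file.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(SamplerConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown sampler config keys: {sorted(unknown)}")
    if seed is not None:
        raw["seed"] = seed
    return SamplerConfig(**raw)
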