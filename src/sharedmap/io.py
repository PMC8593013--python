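"""Reading and writing the package's external formats.

Count tables are long-format CSV with the strict header
``disease,area,gender,age_group,deaths,population``; model and prior
configurations round-trip through YAML; posterior draws persist as a wide
CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    CountData,
    DISEASE_LABELS,
    GENDER_LABELS,
    ModelSpec,
    PriorConfig,
)
from .inference import PosteriorSamples

COUNT_COLUMNS = ["disease", "area", "gender", "age_group", "deaths", "population"]


def _level_index(values: pd.Series, labels: tuple[str, ...], column: str) -> np.ndarray:
    """Map a CSV column to 0-based indices, accepting labels or 1-based ints."""
    out = np.empty(len(values), dtype=int)
    lut = {lab: k for k, lab in enumerate(labels)}
    for pos, v in enumerate(values):
        s = str(v).strip().lower()
        if s in lut:
            out[pos] = lut[s]
        elif s in ("1", "2"):
            out[pos] = int(s) - 1
        else:
            raise ValueError(f"unrecognised {column} value {v!r}")
    return out


def read_counts(path: str | Path) -> CountData:
    """Read a long-format count table CSV into a :class:`CountData`.

    Area and age-group order is first-appearance order; every
    (disease, area, gender, age) combination must appear exactly once.
    """
    df = pd.read_csv(path)
    if list(df.columns) != COUNT_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(COUNT_COLUMNS)}, got {','.join(df.columns)}"
        )
    areas = tuple(dict.fromkeys(df["area"].astype(str)))
    ages = tuple(dict.fromkeys(df["age_group"].astype(str)))
    I, J = len(areas), len(ages)
    d_idx = _level_index(df["disease"], DISEASE_LABELS, "disease")
    g_idx = _level_index(df["gender"], GENDER_LABELS, "gender")
    i_idx = np.array([areas.index(a) for a in df["area"].astype(str)])
    j_idx = np.array([ages.index(a) for a in df["age_group"].astype(str)])
    O = np.full((2, I, 2, J), -1, dtype=np.int64)
    n = np.zeros((2, I, 2, J))
    O[d_idx, i_idx, g_idx, j_idx] = df["deaths"].to_numpy()
    n[d_idx, i_idx, g_idx, j_idx] = df["population"].to_numpy()
    if np.any(O < 0):
        raise ValueError(f"{path}: incomplete lattice (missing cells)")
    if len(df) != 2 * I * 2 * J:
        raise ValueError(f"{path}: duplicated cells in count table")
    return CountData(O=O, n=n, area_ids=areas, age_labels=ages)


def write_counts(data: CountData, path: str | Path) -> None:
    from .reporting import counts_to_frame

    counts_to_frame(data).to_csv(path, index=False)


def write_adjacency(graph, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, j in sorted(graph.edges):
            fh.write(f"{graph.area_ids[i]} {graph.area_ids[j]}\n")


# ---------------------------------------------------------------------------
# configuration round-trip
# ---------------------------------------------------------------------------

def write_config(spec: ModelSpec, priors: PriorConfig, path: str | Path) -> None:
    doc = {"model": spec.to_dict(), "priors": priors.to_dict()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_config(path: str | Path) -> tuple[ModelSpec, PriorConfig]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    spec = ModelSpec.from_dict(doc.get("model", {}))
    priors = PriorConfig.from_dict(doc.get("priors", {}))
    return spec, priors


# ---------------------------------------------------------------------------
# sample persistence
# ---------------------------------------------------------------------------

def save_samples(samples: PosteriorSamples, out_dir: str | Path) -> None:
    """Persist draws as ``samples.csv`` (one column per scalar component,
    one row per draw) with a ``samples_meta.json`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols: dict[str, np.ndarray] = {}
    chains, S = next(iter(samples.draws.values())).shape[:2]
    cols["chain"] = np.repeat(np.arange(chains), S)
    cols["draw"] = np.tile(np.arange(S), chains)
    shapes = {}
    for name, arr in samples.draws.items():
        flat = arr.reshape(chains * S, -1)
        shapes[name] = list(arr.shape[2:])
        if flat.shape[1] == 1:
            cols[name] = flat[:, 0]
        else:
            for k in range(flat.shape[1]):
                idx = np.unravel_index(k, arr.shape[2:])
                cols[f"{name}[{','.join(map(str, idx))}]"] = flat[:, k]
    pd.DataFrame(cols).to_csv(out / "samples.csv", index=False)
    meta = {
        "meta": samples.meta,
        "spec": samples.spec.to_dict(),
        "priors": samples.priors.to_dict(),
        "shapes": shapes,
        "diagnostics": samples.diagnostics,
    }
    (out / "samples_meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_samples(out_dir: str | Path) -> PosteriorSamples:
    out = Path(out_dir)
    meta = json.loads((out / "samples_meta.json").read_text(encoding="utf-8"))
    df = pd.read_csv(out / "samples.csv")
    chains = int(df["chain"].max()) + 1
    S = int(df["draw"].max()) + 1
    draws = {}
    for name, shape in meta["shapes"].items():
        size = int(np.prod(shape)) if shape else 1
        if size == 1 and name in df.columns:
            flat = df[name].to_numpy()[:, None]
        else:
            flat = np.column_stack([
                df[f"{name}[{','.join(map(str, np.unravel_index(k, shape)))}]"].to_numpy()
                for k in range(size)
            ])
        draws[name] = flat.reshape([chains, S] + shape)
    return PosteriorSamples(
        draws=draws,
        spec=ModelSpec.from_dict(meta["spec"]),
        priors=PriorConfig.from_dict(meta["priors"]),
        meta=meta["meta"],
        diagnostics=meta.get("diagnostics", {}),
    )
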