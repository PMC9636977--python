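"""Plain-text I/O for models, designs, and experiment records.

Formats (all line-oriented text, lossless for finite doubles because values
are written with ``repr``-style shortest round-trip formatting):

* interference edge list — TSV with header ``source<TAB>target<TAB>gamma``
  (peer-weight lists use ``c`` as the value column);
* per-individual parameters — CSV with header ``id,alpha,beta``;
* experiment data — CSV ``id,z,Y``; baselines — CSV ``id,alpha``;
* cluster map — CSV ``id,cluster``;
* design and scenario configs — YAML/JSON mappings.

Externally individuals carry arbitrary string ids; the mapping to the
contiguous internal indices 0..n-1 happens here and only here, in the order
the ids appear in the parameter (or experiment) table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .contagion import ContagionModel
from .designs import Design, design_from_config
from .model import HANEModel

Edge = tuple[int, int]


def _ids_of(n: int, ids: Sequence[str] | None) -> list[str]:
    return [str(i) for i in range(n)] if ids is None else [str(x) for x in ids]


# -- edge lists ---------------------------------------------------------
def write_edge_list(path, gamma: dict[Edge, float], ids=None, value_name="gamma"):
    n = 1 + max((max(k, i) for k, i in gamma), default=-1)
    labels = _ids_of(n, ids)
    rows = [
        {"source": labels[k], "target": labels[i], value_name: float(g)}
        for (k, i), g in sorted(gamma.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", value_name]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, ids: Sequence[str], value_name="gamma") -> dict[Edge, float]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for col in ("source", "target", value_name):
        if col not in df.columns:
            raise ValueError(f"edge list {path} is missing column {col!r}")
    index = {str(x): i for i, x in enumerate(ids)}
    gamma: dict[Edge, float] = {}
    for row in df.itertuples(index=False):
        try:
            k = index[row.source]
            i = index[row.target]
        except KeyError as exc:
            raise ValueError(f"edge references unknown id {exc.args[0]!r}") from None
        gamma[(k, i)] = float(getattr(row, value_name))
    return gamma


# -- parameter tables ---------------------------------------------------
def write_params(path, alpha, beta, ids=None):
    labels = _ids_of(len(alpha), ids)
    pd.DataFrame(
        {"id": labels, "alpha": [float(a) for a in alpha],
         "beta": [float(b) for b in beta]}
    ).to_csv(path, index=False)


def read_params(path) -> tuple[list[str], list[float], list[float]]:
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "alpha", "beta"):
        if col not in df.columns:
            raise ValueError(f"parameter table {path} is missing column {col!r}")
    return list(df["id"]), df["alpha"].tolist(), df["beta"].tolist()


def write_model(model: HANEModel, edges_path, params_path):
    ids = _ids_of(model.n, model.ids)
    write_params(params_path, model.alpha.tolist(), model.beta.tolist(), ids)
    write_edge_list(edges_path, {e: float(g) for e, g in model.gamma.items()}, ids)


def read_model(edges_path, params_path) -> HANEModel:
    ids, alpha, beta = read_params(params_path)
    gamma = read_edge_list(edges_path, ids)
    return HANEModel(alpha, beta, gamma, ids=ids)


def write_contagion(cm: ContagionModel, edges_path, params_path, ids=None):
    labels = _ids_of(cm.n, ids)
    write_params(params_path, cm.a.tolist(), cm.b.tolist(), labels)
    write_edge_list(edges_path, cm.c, labels, value_name="c")


def read_contagion(edges_path, params_path) -> ContagionModel:
    ids, a, b = read_params(params_path)
    c = read_edge_list(edges_path, ids, value_name="c")
    return ContagionModel(a, b, c)


# -- experiments --------------------------------------------------------
def write_experiment(path, z, y, ids=None):
    labels = _ids_of(len(y), ids)
    pd.DataFrame(
        {"id": labels, "z": [int(x) for x in z], "Y": [float(v) for v in y]}
    ).to_csv(path, index=False)


def read_experiment(path) -> tuple[list[str], list[int], list[float]]:
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "z", "Y"):
        if col not in df.columns:
            raise ValueError(f"experiment table {path} is missing column {col!r}")
    return list(df["id"]), df["z"].astype(int).tolist(), df["Y"].tolist()


def write_baselines(path, alpha, ids=None):
    labels = _ids_of(len(alpha), ids)
    pd.DataFrame({"id": labels, "alpha": [float(a) for a in alpha]}).to_csv(
        path, index=False
    )


def read_baselines(path) -> tuple[list[str], list[float]]:
    df = pd.read_csv(path, dtype={"id": str})
    return list(df["id"]), df["alpha"].tolist()


# -- cluster maps and configs -------------------------------------------
def write_clusters(path, labels, ids=None):
    idl = _ids_of(len(labels), ids)
    pd.DataFrame({"id": idl, "cluster": list(labels)}).to_csv(path, index=False)


def read_clusters(path) -> tuple[list[str], list]:
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "cluster"):
        if col not in df.columns:
            raise ValueError(f"cluster map {path} is missing column {col!r}")
    return list(df["id"]), df["cluster"].tolist()


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_design(source, ids: Sequence[str] | None = None) -> Design:
    """Design from a config mapping or YAML/JSON path.

    A ``clusters`` entry may be an inline list (aligned with ``ids`` /
    index order) or the path of a ``id,cluster`` CSV, in which case the
    labels are re-ordered to match ``ids``.
    """
    cfg = dict(load_config(source)) if not isinstance(source, dict) else dict(source)
    clusters = cfg.get("clusters")
    if isinstance(clusters, str):
        cid, labels = read_clusters(clusters)
        if ids is not None:
            lookup = dict(zip(cid, labels))
            try:
                labels = [lookup[str(x)] for x in ids]
            except KeyError as exc:
                raise ValueError(
                    f"cluster map is missing id {exc.args[0]!r}"
                ) from None
        cfg["clusters"] = labels
    return design_from_config(cfg)
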