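"""TSV / SIF round-tripping for all pipeline artifacts.

Conventions: tab separators, '.' decimal, UTF-8, header row; the first
column holds node ids for matrices.  Undefined entries (matrix
diagonals) are serialized as the token ``NA`` — "not modeled" is
distinct from "absent".  SIF rows are written source -> target, i.e.
column j -> row i for adjacency A[i, j] = 1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import ConnectionCoefficientMatrix, StochasticMraResult
from .data import (
    DataError,
    GlobalResponseMatrix,
    PerturbationDesign,
    SteadyStateTable,
)
from .inference import CalledNetwork, PosteriorEdgeMatrix
from .sampler import ChainTrace

NA = "NA"


def read_steady_state_table(path: str | Path) -> SteadyStateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SteadyStateTable(
        df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_steady_state_table(table: SteadyStateTable, path: str | Path) -> None:
    pd.DataFrame(table.values, index=table.node_ids, columns=table.experiment_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_design(path: str | Path) -> PerturbationDesign:
    df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str, "target_node": str})
    for col in ("experiment_id", "target_node"):
        if col not in df.columns:
            raise DataError(f"design file {path} is missing column {col!r}")
    if df["experiment_id"].duplicated().any():
        dups = df.loc[df["experiment_id"].duplicated(), "experiment_id"].tolist()
        raise DataError(
            f"experiments listed more than once (multi-target designs are "
            f"not supported): {dups}"
        )
    target_of = dict(zip(df["experiment_id"], df["target_node"]))
    efficiency = {}
    replicate = {}
    if "efficiency" in df.columns:
        for e, v in zip(df["experiment_id"], df["efficiency"]):
            if pd.notna(v):
                efficiency[e] = float(v)
    if "replicate" in df.columns:
        for e, v in zip(df["experiment_id"], df["replicate"]):
            if pd.notna(v):
                replicate[e] = int(v)
    return PerturbationDesign(target_of, efficiency, replicate)


def write_design(design: PerturbationDesign, path: str | Path) -> None:
    rows = [
        {
            "experiment_id": e,
            "target_node": t,
            "efficiency": design.efficiency.get(e, np.nan),
            "replicate": design.replicate.get(e, np.nan),
        }
        for e, t in design.target_of.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=NA)


def read_response_matrix(path: str | Path, standardized: bool = False) -> GlobalResponseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GlobalResponseMatrix(
        df.to_numpy(float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        standardized=standardized,
    )


def write_response_matrix(resp: GlobalResponseMatrix, path: str | Path) -> None:
    pd.DataFrame(resp.R, index=resp.node_ids, columns=resp.experiment_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def write_probability_matrix(pem: PosteriorEdgeMatrix, path: str | Path) -> None:
    pd.DataFrame(pem.P, index=pem.node_ids, columns=pem.node_ids).to_csv(
        path, sep="\t", na_rep=NA, float_format="%.6f"
    )


def read_probability_matrix(path: str | Path) -> PosteriorEdgeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    P = df.to_numpy(float)
    np.fill_diagonal(P, np.nan)
    return PosteriorEdgeMatrix(P, [str(i) for i in df.index])


def write_adjacency(
    A: np.ndarray, node_ids: list[str], path: str | Path, diag_na: bool = True
) -> None:
    df = pd.DataFrame(np.asarray(A, dtype=object), index=node_ids, columns=node_ids)
    if diag_na:
        for i in range(len(node_ids)):
            df.iat[i, i] = np.nan
    df.to_csv(path, sep="\t", na_rep=NA)


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    A = df.fillna(0).to_numpy(float)
    return A, [str(i) for i in df.index]


def write_sif(called: CalledNetwork, path: str | Path, tag: str = "influences") -> None:
    lines = []
    for i, target in enumerate(called.node_ids):
        for j, source in enumerate(called.node_ids):
            if called.A[i, j]:
                lines.append(f"{source}\t{tag}\t{target}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_signed_sif(adjacency: np.ndarray, node_ids: list[str], path: str | Path) -> None:
    lines = []
    for i in range(len(node_ids)):
        for j in range(len(node_ids)):
            if adjacency[i, j] > 0:
                lines.append(f"{node_ids[j]}\tactivates\t{node_ids[i]}")
            elif adjacency[i, j] < 0:
                lines.append(f"{node_ids[j]}\tinhibits\t{node_ids[i]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_trace(trace: ChainTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sweep\tbits\tlog_score\n")
        for t in range(trace.n_sweeps):
            bits = "".join(str(int(b)) for b in trace.samples[t])
            fh.write(f"{t}\t{bits}\t{trace.log_scores[t]:.10g}\n")


def write_connection_coefficients(
    ccm: ConnectionCoefficientMatrix, path: str | Path
) -> None:
    pd.DataFrame(ccm.r, index=ccm.node_ids, columns=ccm.node_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def write_stochastic_mra_table(res: StochasticMraResult, path: str | Path) -> None:
    rows = []
    n = len(res.node_ids)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows.append(
                {
                    "coefficient": f"r[{res.node_ids[i]},{res.node_ids[j]}]",
                    "target": res.node_ids[i],
                    "source": res.node_ids[j],
                    "mean": res.mean[i, j],
                    "sd": res.sd[i, j],
                    "n_retained": res.n_retained[i, j],
                    "p": res.p_value[i, j],
                    "p_adj": res.p_adjusted[i, j],
                    "identifiable": bool(res.identifiable[i, j]),
                    "sign": int(res.sign[i, j]),
                    "called": bool(res.called[i, j]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6g")
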