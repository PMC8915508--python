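"""Multimorbidity network: sparse co-occurrence counting, relative-risk edges
with Katz-style 99% confidence intervals, and eigenvector centrality.

Diseases are nodes; an edge connects two chronic diseases that co-occur in
the same patients more often than expected under independence.  The edge
weight is the relative risk

    RR_ij = C_ij · N / (C_i · C_j)

where C_i and C_j count the patients carrying each disease, C_ij counts the
patients carrying both, and N is the cohort size.  The multiplicative
confidence interval is RR · exp(±z·σ) with z = 2.58 for the 99% level.  Two
dispersion conventions ship for σ (see :func:`katz_ci`).

Co-occurrence counts come from a single sparse transpose-product of the
binary patient×disease matrix, which keeps construction tractable when the
matrix has hundreds of thousands of rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .records import AdmissionRecord, ChronicDiseaseCatalog

Z_99 = 2.58
SigmaMode = Literal["as_printed", "sqrt"]
EdgeRule = Literal["ci_low_gt_1", "rr_gt_1", "all"]


@dataclass
class PatientDiseaseMatrix:
    """Binary sparse patients × chronic-diseases indicator matrix.

    A cell is 1 iff the patient carries the disease in *any* record of the
    construction era, at any diagnosis position (on admission or acquired
    in hospital alike) — chronic-disease semantics.
    """

    matrix: sparse.csc_matrix          # binary, CSC for column slicing
    patient_ids: list[str]
    disease_codes: list[str]

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    def column_counts(self) -> np.ndarray:
        """C_i: number of patients carrying each disease."""
        return np.asarray(self.matrix.sum(axis=0)).ravel().astype(np.int64)


def build_patient_disease_matrix(
    records: Sequence[AdmissionRecord],
    catalog: ChronicDiseaseCatalog,
    era: tuple[date, date] | None = None,
) -> PatientDiseaseMatrix:
    """OR-aggregate each patient's chronic diagnoses over the era's records.

    Columns are restricted to catalog codes actually observed in the era;
    rows to patients with at least one chronic diagnosis there.
    """
    rows: dict[str, set[str]] = {}
    for r in records:
        if era is not None and not (era[0] <= r.admission_date <= era[1]):
            continue
        chronic = r.all_codes() & catalog.codes
        if chronic:
            rows.setdefault(r.patient_id, set()).update(chronic)
    if not rows:
        raise ValueError("no records with chronic diagnoses in the era")

    patient_ids = sorted(rows)
    disease_codes = sorted(set().union(*rows.values()))
    col_of = {c: k for k, c in enumerate(disease_codes)}
    ri, ci = [], []
    for i, pid in enumerate(patient_ids):
        for c in rows[pid]:
            ri.append(i)
            ci.append(col_of[c])
    m = sparse.csc_matrix(
        (np.ones(len(ri), dtype=np.int8), (ri, ci)),
        shape=(len(patient_ids), len(disease_codes)),
    )
    return PatientDiseaseMatrix(m, patient_ids, disease_codes)


def cooccurrence_counts(M: PatientDiseaseMatrix) -> np.ndarray:
    """Disease×disease count table Mᵀ·M.

    Diagonal (i,i) = C_i; off-diagonal (i,j) = C_ij, the number of patients
    carrying both diseases.  Symmetric by construction.
    """
    mt = M.matrix.astype(np.int64)
    return np.asarray((mt.T @ mt).todense())


def relative_risk(c_ij: int, c_i: int, c_j: int, n: int) -> float:
    """RR of co-occurrence: observed joint count over its independence
    expectation, C_ij·N/(C_i·C_j)."""
    if c_i < 1 or c_j < 1 or n < 1:
        raise ValueError("RR undefined: C_i, C_j and N must all be ≥ 1")
    if c_ij > min(c_i, c_j):
        raise ValueError("C_ij cannot exceed min(C_i, C_j)")
    return c_ij * n / (c_i * c_j)


def katz_dispersion(c_ij: int, c_i: int, c_j: int, n: int,
                    sigma_mode: SigmaMode = "as_printed") -> float:
    """Dispersion term σ of the multiplicative RR interval.

    ``as_printed`` (default) is the sum 1/C_ij + 1/(C_i·C_j) − 1/N − 1/N²
    used directly; ``sqrt`` takes the square root of that sum, treating it
    as a variance so the interval behaves like a log-scale Wald CI.
    """
    if c_ij < 1:
        raise ValueError("CI undefined when C_ij = 0")
    s = 1.0 / c_ij + 1.0 / (c_i * c_j) - 1.0 / n - 1.0 / n**2
    if sigma_mode == "as_printed":
        return s
    if sigma_mode == "sqrt":
        return math.sqrt(max(s, 0.0))
    raise ValueError(f"unknown sigma_mode {sigma_mode!r}")


def katz_ci(rr: float, c_ij: int, c_i: int, c_j: int, n: int,
            z: float = Z_99, sigma_mode: SigmaMode = "as_printed",
            ) -> tuple[float, float]:
    """Multiplicative confidence interval [RR·e^(−zσ), RR·e^(+zσ)]."""
    sigma = katz_dispersion(c_ij, c_i, c_j, n, sigma_mode)
    return rr * math.exp(-z * sigma), rr * math.exp(z * sigma)


def build_mn(
    M: PatientDiseaseMatrix,
    min_pair_count: int = 1,
    edge_rule: EdgeRule = "ci_low_gt_1",
    sigma_mode: SigmaMode = "sqrt",
    z: float = Z_99,
) -> nx.Graph:
    """Build the multimorbidity network from the patient–disease matrix.

    Nodes are diseases with C_i ≥ 1 (attribute ``count``); candidate edges
    are pairs with C_ij ≥ ``min_pair_count``, retained per ``edge_rule``:

    - ``ci_low_gt_1`` (default): the CI lower bound exceeds 1, i.e. the
      co-occurrence is significantly super-independent at the z level.
      Retention defaults to the ``sqrt`` dispersion, the variant with
      actual coverage; the printed-sum variant is available.
    - ``rr_gt_1``: point estimate above 1.
    - ``all``: every candidate pair.

    Every retained edge stores C_ij, RR, ci_low and ci_high.
    """
    counts = cooccurrence_counts(M)
    n = M.n_patients
    codes = M.disease_codes
    c = np.diag(counts)

    g = nx.Graph()
    for k, code in enumerate(codes):
        if c[k] >= 1:
            g.add_node(code, count=int(c[k]))

    iu, ju = np.triu_indices(len(codes), k=1)
    mask = counts[iu, ju] >= max(min_pair_count, 1)
    for i, j in zip(iu[mask], ju[mask]):
        c_ij = int(counts[i, j])
        rr = relative_risk(c_ij, int(c[i]), int(c[j]), n)
        lo, hi = katz_ci(rr, c_ij, int(c[i]), int(c[j]), n, z, sigma_mode)
        if edge_rule == "ci_low_gt_1" and not lo > 1.0:
            continue
        if edge_rule == "rr_gt_1" and not rr > 1.0:
            continue
        g.add_edge(codes[i], codes[j], c_ij=c_ij, rr=rr, ci_low=lo, ci_high=hi)
    return g


def eigenvector_centrality(
    g: nx.Graph,
    weight_mode: Literal["rr", "binary"] = "rr",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Eigenvector centrality by power iteration on the (RR-weighted)
    adjacency matrix.

    The score vector is the principal eigenvector of A: iterate x ← Ax/‖Ax‖
    from the all-ones vector until the L1 change of successive iterates is
    below ``tol``.  Disconnected graphs are handled per connected component,
    each component's scores Euclidean-normalized independently; isolated
    nodes score 0.  All scores are nonnegative.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("centrality of an empty graph is undefined")
    weight = "rr" if weight_mode == "rr" else None
    scores: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            scores[nodes[0]] = 0.0 if g.degree(nodes[0]) == 0 else 1.0
            continue
        a = nx.to_numpy_array(g, nodelist=nodes, weight=weight)
        # identity shift: same principal eigenvector, but breaks the
        # period-2 oscillation power iteration suffers on bipartite graphs
        a = a + np.eye(len(nodes))
        x = np.ones(len(nodes))
        x /= np.linalg.norm(x)
        for _ in range(max_iter):
            y = a @ x
            ny = np.linalg.norm(y)
            if ny == 0.0:        # no edges inside the component (cannot happen
                break            # for a connected component of size ≥ 2)
            y /= ny
            if np.abs(y - x).sum() < tol:
                x = y
                break
            x = y
        else:
            raise RuntimeError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(residual {np.abs(a @ x / np.linalg.norm(a @ x) - x).sum():.3e})"
            )
        x = np.abs(x)            # principal eigenvector of a nonnegative
        x /= np.linalg.norm(x)   # matrix is nonnegative; fix sign, renorm
        scores.update(zip(nodes, x.tolist()))
    return scores


def edge_table(g: nx.Graph) -> pd.DataFrame:
    """Plain edge-list export (disease_i, disease_j, C_ij, RR, CI bounds)."""
    rows = [
        {"disease_i": u, "disease_j": v, "c_ij": d["c_ij"], "rr": d["rr"],
         "ci_low": d["ci_low"], "ci_high": d["ci_high"]}
        for u, v, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(
        rows, columns=["disease_i", "disease_j", "c_ij", "rr", "ci_low", "ci_high"]
    )


def node_table(g: nx.Graph, evc: dict[str, float] | None = None) -> pd.DataFrame:
    rows = [
        {"code": v, "count": d.get("count", 0),
         "evc": (evc or {}).get(v, float("nan"))}
        for v, d in sorted(g.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["code", "count", "evc"])
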