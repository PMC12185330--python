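"""Pedigree graphs, kinship coefficients and relative enumeration.

The family genetic risk scores downstream are weighted sums over a proband's
1st–5th-degree relatives, so the two jobs of this module are (i) the classical
recursive kinship coefficient phi and (ii) enumerating, for every proband, all
relatives with relatedness 2*phi >= 2**-5 together with their degree class.

Two code paths compute the same quantity:

* :func:`kinship` — the textbook memoised recursion, valid for any pedigree
  (including inbred ones); used for single pairs and small pedigrees.
* :func:`relative_links` — a vectorised common-ancestor path sum used at
  registry scale. It requires an outbred pedigree (no individual descends from
  the same ancestor along two distinct lines), which the synthetic generator
  guarantees and which the function verifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_DEGREE = 5

# relatedness 2*phi for the centre of each degree bin, degree 1..5
_DEGREE_RELATEDNESS = {1: 0.5, 2: 0.25, 3: 0.125, 4: 0.0625, 5: 0.03125}


class UnknownIdError(KeyError):
    """Raised when an id is not present in the pedigree."""


@dataclass
class PedigreeGraph:
    """Parent mapping with a parents-before-children topological order.

    Parameters
    ----------
    parents:
        Mapping ``id -> (father_id | None, mother_id | None)``. Founders have
        both entries ``None``; single known parents are allowed.
    """

    parents: dict[int, tuple[int | None, int | None]]
    order: list[int] = field(init=False)
    _depth: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._depth = {}
        for pid in self.parents:
            self._resolve_depth(pid)
        self.order = sorted(self.parents, key=lambda i: (self._depth[i], i))
        self._children: dict[int, list[int]] = {}
        for child, (f, m) in self.parents.items():
            for par in (f, m):
                if par is not None:
                    if par not in self.parents:
                        raise UnknownIdError(
                            f"parent {par} of {child} missing from pedigree"
                        )
                    self._children.setdefault(par, []).append(child)
        self._kin_cache: dict[tuple[int, int], float] = {}

    def _resolve_depth(self, pid: int, _stack: frozenset = frozenset()) -> int:
        if pid in self._depth:
            return self._depth[pid]
        if pid in _stack:
            raise ValueError(f"pedigree contains a cycle through id {pid}")
        f, m = self.parents.get(pid, (None, None))
        stack = _stack | {pid}
        d = 0
        for par in (f, m):
            if par is not None:
                d = max(d, self._resolve_depth(par, stack) + 1)
        self._depth[pid] = d
        return d

    @classmethod
    def from_frame(cls, pedigree: pd.DataFrame) -> "PedigreeGraph":
        """Build from a frame with columns id, father_id, mother_id (NaN = unknown)."""
        parents = {}
        for row in pedigree.itertuples(index=False):
            f = None if pd.isna(row.father_id) else int(row.father_id)
            m = None if pd.isna(row.mother_id) else int(row.mother_id)
            parents[int(row.id)] = (f, m)
        return cls(parents)

    def children(self, pid: int) -> list[int]:
        return self._children.get(pid, [])

    def __contains__(self, pid: int) -> bool:
        return pid in self.parents


@dataclass(frozen=True)
class RelativeLink:
    """One proband–relative pair with its kinship and degree class."""

    proband: int
    relative: int
    phi: float
    degree: int
    cohab_years: float = 0.0

    @property
    def relatedness(self) -> float:
        return 2.0 * self.phi


def kinship(graph: PedigreeGraph, i: int, j: int) -> float:
    """Kinship coefficient phi(i, j) by the standard recursion.

    phi(i, i) = 0.5 * (1 + phi(father_i, mother_i)); for i != j the recursion
    descends through the parents of whichever individual is later in the
    topological order, so it terminates at founders. Symmetric in (i, j).
    """
    for pid in (i, j):
        if pid not in graph:
            raise UnknownIdError(f"id {pid} not in pedigree")
    return _kinship_rec(graph, i, j)


def _kinship_rec(graph: PedigreeGraph, i: int, j: int) -> float:
    key = (i, j) if i <= j else (j, i)
    cache = graph._kin_cache
    if key in cache:
        return cache[key]
    depth = graph._depth
    if i == j:
        f, m = graph.parents[i]
        inb = _kinship_rec(graph, f, m) if (f is not None and m is not None) else 0.0
        val = 0.5 * (1.0 + inb)
    else:
        # recurse through the lower individual (never an ancestor of the other)
        if (depth[i], i) < (depth[j], j):
            i, j = j, i
        f, m = graph.parents[i]
        val = 0.0
        if f is not None:
            val += 0.5 * _kinship_rec(graph, f, j)
        if m is not None:
            val += 0.5 * _kinship_rec(graph, m, j)
    cache[key] = val
    return val


def degree_of_relatedness(relatedness: float) -> int | None:
    """Map relatedness 2*phi to a degree class 1..5 (nearest bin on log2 scale).

    Returns None when the relatedness is below half the 5th-degree bin
    (i.e. the pair does not count as a relative).
    """
    if relatedness <= 0:
        return None
    d = round(-np.log2(relatedness))
    if d < 1:
        d = 1
    if d > MAX_DEGREE:
        return None
    return int(d)


def enumerate_relatives(
    graph: PedigreeGraph, proband: int, max_degree: int = MAX_DEGREE
) -> list[RelativeLink]:
    """All relatives of ``proband`` with relatedness >= the ``max_degree`` bin.

    Candidates are restricted to individuals sharing at least one ancestor with
    the proband (including ancestors and descendants themselves); kinship for
    each candidate is computed by the exact recursion.
    """
    if proband not in graph:
        raise UnknownIdError(f"id {proband} not in pedigree")
    anc = _ancestors(graph, proband, max_degree)
    candidates: set[int] = set()
    for a in anc:
        candidates |= _descendants(graph, a, max_degree + 1)
    candidates.discard(proband)
    cutoff = _DEGREE_RELATEDNESS[max_degree] * (2 ** -0.5)  # half-bin on log2 scale
    links = []
    for rel in sorted(candidates):
        phi = kinship(graph, proband, rel)
        r = 2.0 * phi
        if r < cutoff:
            continue
        deg = degree_of_relatedness(r)
        if deg is None or deg > max_degree:
            continue
        links.append(RelativeLink(proband=proband, relative=rel, phi=phi, degree=deg))
    return links


def _ancestors(graph: PedigreeGraph, pid: int, max_up: int) -> set[int]:
    out = {pid}
    frontier = {pid}
    for _ in range(max_up):
        nxt = set()
        for p in frontier:
            for par in graph.parents[p]:
                if par is not None:
                    nxt.add(par)
        out |= nxt
        frontier = nxt
        if not frontier:
            break
    return out


def _descendants(graph: PedigreeGraph, pid: int, max_down: int) -> set[int]:
    out = {pid}
    frontier = {pid}
    for _ in range(max_down):
        nxt = set()
        for p in frontier:
            nxt.update(graph.children(p))
        out |= nxt
        frontier = nxt
        if not frontier:
            break
    return out


def relative_links(
    pedigree: pd.DataFrame,
    probands: np.ndarray | pd.Series | list[int] | None = None,
    max_degree: int = MAX_DEGREE,
) -> pd.DataFrame:
    """Vectorised proband–relative link table for an outbred pedigree.

    Computes phi(i, j) as a sum over common ancestors A of
    ``2**-(d_i + d_j + 1)`` where ``d_x`` is the (unique, because the pedigree
    is outbred) path length from x up to A, counting only ancestors where the
    two paths diverge immediately below A. This is Wright's path-counting
    formula specialised to pedigrees without inbreeding loops.

    Parameters
    ----------
    pedigree:
        Frame with columns id, father_id, mother_id.
    probands:
        Ids to enumerate relatives for; defaults to every id.

    Returns
    -------
    DataFrame with columns proband, relative, phi, degree.
    """
    ped = pedigree[["id", "father_id", "mother_id"]].copy()
    ids = ped["id"].to_numpy(np.int64)
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree table")

    # long parent table: (child, parent)
    par = pd.concat(
        [
            ped[["id", "father_id"]].rename(columns={"father_id": "anc"}),
            ped[["id", "mother_id"]].rename(columns={"mother_id": "anc"}),
        ]
    ).dropna()
    par = par.astype({"id": np.int64, "anc": np.int64})

    # iterate: ancestor entries (person, anc, depth, below) where `below` is the
    # child of `anc` on the person's (unique) path up to `anc`; self has depth 0.
    base = pd.DataFrame(
        {"person": ids, "anc": ids, "d": 0, "below": ids}
    )
    layers = [base]
    frontier = par.rename(columns={"id": "person"}).copy()
    frontier["d"] = 1
    frontier["below"] = frontier["person"]
    for depth in range(1, max_degree + 1):
        if frontier.empty:
            break
        layers.append(frontier[["person", "anc", "d", "below"]])
        if depth == max_degree:
            break
        nxt = frontier.merge(
            par.rename(columns={"id": "anc", "anc": "anc_next"}), on="anc", how="inner"
        )
        nxt["below"] = nxt["anc"]
        nxt = nxt.rename(columns={"anc": "_drop", "anc_next": "anc"})
        nxt["d"] = depth + 1
        frontier = nxt[["person", "anc", "d", "below"]]
    anc_tab = pd.concat(layers, ignore_index=True)

    dup = anc_tab.duplicated(subset=["person", "anc"], keep=False)
    if dup.any():
        bad = anc_tab.loc[dup, "person"].iloc[0]
        raise ValueError(
            f"pedigree is inbred (id {bad} reaches an ancestor along two lines); "
            "use enumerate_relatives() for inbred pedigrees"
        )

    anc_tab = anc_tab.astype(
        {"person": np.int64, "anc": np.int64, "d": np.int8, "below": np.int64}
    )
    left = anc_tab
    if probands is not None:
        pset = np.asarray(probands, dtype=np.int64)
        left = anc_tab[anc_tab["person"].isin(pset)]

    # self-join on the common ancestor, chunked by ancestor hash to bound the
    # size of the intermediate pair table
    n_chunks = -(-len(left) // 150_000)
    anc_hash = anc_tab["anc"].to_numpy() % n_chunks
    left_hash = left["anc"].to_numpy() % n_chunks
    parts = []
    for c in range(n_chunks):
        right_c = anc_tab[anc_hash == c]
        left_c = left[left_hash == c]
        if left_c.empty or right_c.empty:
            continue
        pairs = left_c.merge(right_c, on="anc", suffixes=("_p", "_r"))
        # exclude paths through an intermediate common ancestor: keep only
        # pairs whose paths diverge at `anc` itself (or where one member IS
        # the ancestor), and drop self-pairs
        keep = (pairs["person_p"] != pairs["person_r"]) & (
            (pairs["below_p"] != pairs["below_r"])
            | (pairs["d_p"] == 0)
            | (pairs["d_r"] == 0)
        )
        pairs = pairs[keep]
        contrib = np.ldexp(
            1.0, -(pairs["d_p"].to_numpy(np.int64) + pairs["d_r"].to_numpy(np.int64) + 1)
        )
        part = (
            pd.DataFrame(
                {
                    "proband": pairs["person_p"].to_numpy(),
                    "relative": pairs["person_r"].to_numpy(),
                    "phi": contrib,
                }
            )
            .groupby(["proband", "relative"], sort=False)["phi"]
            .sum()
        )
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=["proband", "relative", "phi", "degree"])
    phi = pd.concat(parts).groupby(["proband", "relative"]).sum().reset_index()
    rel = 2.0 * phi["phi"].to_numpy()
    cutoff = _DEGREE_RELATEDNESS[max_degree] * (2 ** -0.5)
    phi = phi[rel >= cutoff].copy()
    with np.errstate(divide="ignore"):
        deg = np.rint(-np.log2(2.0 * phi["phi"].to_numpy())).astype(int)
    deg = np.clip(deg, 1, MAX_DEGREE)
    phi["degree"] = deg
    keep = phi["degree"] <= max_degree
    out = phi[keep].sort_values(["proband", "relative"]).reset_index(drop=True)
    return out


def attach_cohab_years(links: pd.DataFrame, cohab: pd.DataFrame) -> pd.DataFrame:
    """Merge co-residence years onto a link table (missing pairs get 0).

    ``cohab`` has columns id_a, id_b, years; pairs are unordered.
    """
    if cohab.empty:
        out = links.copy()
        out["cohab_years"] = 0.0
        return out
    c = pd.concat(
        [
            cohab.rename(columns={"id_a": "proband", "id_b": "relative"}),
            cohab.rename(columns={"id_b": "proband", "id_a": "relative"}),
        ],
        ignore_index=True,
    )[["proband", "relative", "years"]]
    c = c.drop_duplicates(subset=["proband", "relative"])
    out = links.merge(c, on=["proband", "relative"], how="left")
    out["cohab_years"] = out.pop("years").fillna(0.0)
    return out
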