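"""Patient-sharing network construction, thresholding and layering.

A patient-sharing network has one node per (physician, specialty,
municipality) combination and an undirected edge between two physicians
weighted by the number of *distinct* patients who visited both within a
±3-month window (91 days, inclusive).  Spurious ties are pruned by requiring
a minimum number of shared patients ``p`` and a maximum great-circle distance
``d`` between the physicians' municipalities; within-specialty layers drop
all cross-specialty edges.

Networks are :class:`networkx.Graph` objects with node attributes
``specialty`` and ``municipality`` and integer edge attribute ``weight``.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, MunicipalityLookupError, ValidationError

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometres; accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def parse_contact_dates(contacts: pd.DataFrame) -> pd.Series:
    """Parse the ``date`` column, naming the first offending row on failure."""
    parsed = pd.to_datetime(contacts["date"], errors="coerce", format="mixed")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValidationError(
            f"unparseable visit date at row {row}: {contacts['date'].iloc[row]!r}"
        )
    return parsed


def build_sharing_network(
    contacts: pd.DataFrame,
    window_days: int = 91,
    physicians: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build the weighted patient-sharing network from visit records.

    For every unordered physician pair the edge weight is the number of
    distinct patients with at least one visit to each of the two physicians
    no more than ``window_days`` apart (boundary inclusive; 91 days stands in
    for the 3 calendar months before and after an anchor visit).  A patient
    co-visiting a pair in several separate windows still counts once.

    Parameters
    ----------
    contacts
        Columns ``patient_id``, ``physician_id``, ``date``,
        ``municipality_id``.
    window_days
        Half-width of the co-visit window in days.
    physicians
        Optional attribute table; when given, ``specialty`` (and, for
        visit-less physicians, isolated nodes) are attached from it.
    """
    if contacts.empty:
        raise ValidationError("contact table is empty")
    dates = parse_contact_dates(contacts)

    phys_codes, phys_index = pd.factorize(contacts["physician_id"], sort=True)
    day = (dates - dates.min()).dt.days.to_numpy()
    patient_codes = pd.factorize(contacts["patient_id"])[0]

    order = np.lexsort((day, patient_codes))
    p_sorted = patient_codes[order]
    d_sorted = day[order]
    f_sorted = phys_codes[order]

    weights: dict[tuple[int, int], int] = {}
    starts = np.flatnonzero(np.r_[True, p_sorted[1:] != p_sorted[:-1]])
    bounds = np.r_[starts, p_sorted.size]
    for b, e in zip(bounds[:-1], bounds[1:]):
        days_p = d_sorted[b:e]
        phys_p = f_sorted[b:e]
        pairs: set[tuple[int, int]] = set()
        # days_p ascending: pair each visit with later visits inside the window
        hi = np.searchsorted(days_p, days_p + window_days, side="right")
        for i in range(days_p.size):
            fi = phys_p[i]
            for j in range(i + 1, hi[i]):
                fj = phys_p[j]
                if fi != fj:
                    pairs.add((fi, fj) if fi < fj else (fj, fi))
        for pair in pairs:
            weights[pair] = weights.get(pair, 0) + 1

    net = nx.Graph()
    muni = dict(zip(contacts["physician_id"], contacts["municipality_id"]))
    for pid in phys_index:
        net.add_node(pid, municipality=muni[pid])
    for (i, j), w in weights.items():
        net.add_edge(phys_index[i], phys_index[j], weight=int(w))

    if physicians is not None:
        spec = dict(zip(physicians["physician_id"], physicians["specialty"]))
        muni_tab = dict(zip(physicians["physician_id"],
                            physicians["municipality_id"]))
        for pid in physicians["physician_id"]:
            if pid not in net:
                net.add_node(pid, municipality=muni_tab[pid])
            net.nodes[pid]["specialty"] = spec[pid]
    return net


def municipality_coordinates(municipalities: pd.DataFrame) -> dict[str, tuple[float, float]]:
    return {
        str(m): (float(la), float(lo))
        for m, la, lo in zip(municipalities["municipality_id"],
                             municipalities["lat"], municipalities["lon"])
    }


def threshold_network(
    net: nx.Graph,
    p: int,
    d: float,
    municipalities: pd.DataFrame,
) -> nx.Graph:
    """Remove edges with weight below ``p`` or municipality distance above ``d``.

    ``p >= 1`` is the minimum number of shared patients, ``d > 0`` the
    maximum great-circle distance in km (boundary inclusive).  Surviving
    weights are unchanged.  Raises :class:`MunicipalityLookupError` naming
    the ID if a node's municipality is missing from the gazetteer.
    """
    if p < 1:
        raise ConfigurationError(f"p must be >= 1, got {p}")
    if d <= 0:
        raise ConfigurationError(f"d must be positive, got {d}")
    coords = municipality_coordinates(municipalities)
    for node, data in net.nodes(data=True):
        if str(data["municipality"]) not in coords:
            raise MunicipalityLookupError(
                f"municipality {data['municipality']!r} of node {node!r} "
                "has no coordinates"
            )
    out = net.copy()
    drop = []
    for u, v, w in out.edges(data="weight"):
        la1, lo1 = coords[str(out.nodes[u]["municipality"])]
        la2, lo2 = coords[str(out.nodes[v]["municipality"])]
        if w < p or haversine_km(la1, lo1, la2, lo2) > d:
            drop.append((u, v))
    out.remove_edges_from(drop)
    return out


def specialty_layer(net: nx.Graph, specialty: str) -> nx.Graph:
    """Restrict the network to one specialty's physicians and their edges."""
    present = {data.get("specialty") for _, data in net.nodes(data=True)}
    if specialty not in present:
        raise ConfigurationError(
            f"unknown specialty {specialty!r}; present: {sorted(filter(None, present))}"
        )
    nodes = [n for n, data in net.nodes(data=True)
             if data.get("specialty") == specialty]
    return net.subgraph(nodes).copy()


def giant_component(net: nx.Graph) -> dict[str, bool]:
    """Flag membership of the largest connected component, per node.

    Isolated physicians stay in the node set (they remain reachable through
    random re-location when alpha > 0); the returned mapping just marks them
    as outside the giant component.  Ties are broken toward the component
    containing the smallest node label.
    """
    if net.number_of_nodes() == 0:
        return {}
    comps = sorted(nx.connected_components(net),
                   key=lambda c: (-len(c), min(map(str, c))))
    giant = comps[0]
    return {n: (n in giant) for n in net.nodes}


# ---------------------------------------------------------------------------
# import/export

def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Write the weighted edge list as CSV (src_id, dst_id, weight)."""
    rows = sorted((str(u), str(v), int(w)) if str(u) <= str(v)
                  else (str(v), str(u), int(w))
                  for u, v, w in net.edges(data="weight"))
    pd.DataFrame(rows, columns=["src_id", "dst_id", "weight"]).to_csv(
        path, index=False)


def write_node_table(net: nx.Graph, path: str | Path) -> None:
    rows = [(str(n), d.get("specialty", ""), str(d.get("municipality", "")))
            for n, d in sorted(net.nodes(data=True), key=lambda x: str(x[0]))]
    pd.DataFrame(rows, columns=["physician_id", "specialty",
                                "municipality_id"]).to_csv(path, index=False)


def read_edgelist(edge_path: str | Path,
                  node_path: str | Path | None = None) -> nx.Graph:
    """Read a network written by :func:`write_edgelist` / :func:`write_node_table`."""
    net = nx.Graph()
    if node_path is not None:
        nodes = pd.read_csv(node_path, dtype=str).fillna("")
        for _, row in nodes.iterrows():
            net.add_node(row["physician_id"],
                         specialty=row["specialty"] or None,
                         municipality=row["municipality_id"])
    edges = pd.read_csv(edge_path, dtype={"src_id": str, "dst_id": str})
    for _, row in edges.iterrows():
        net.add_edge(row["src_id"], row["dst_id"], weight=int(row["weight"]))
    return net


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    out = net.copy()
    for _, data in out.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
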