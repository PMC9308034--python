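from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import carenet as cn


def make_contacts(rows) -> pd.DataFrame:
    """Build a contact table from (patient, physician, date[, municipality])."""
    out = []
    for row in rows:
        pat, phys, date = row[:3]
        muni = row[3] if len(row) > 3 else "10001"
        out.append((pat, phys, date, muni))
    return pd.DataFrame(out, columns=["patient_id", "physician_id", "date",
                                      "municipality_id"])


def make_municipalities(ids_coords) -> pd.DataFrame:
    """Gazetteer from (municipality_id, lat, lon) triples."""
    return pd.DataFrame(ids_coords, columns=["municipality_id", "lat", "lon"])


def make_system(W, C, N, munis=None, coords=None, specialty="GP"):
    """Compile a System straight from an adjacency matrix and capacities.

    By default every physician sits in the same municipality, so the
    distance rule never interferes.
    """
    n = len(C)
    if munis is None:
        munis = ["10001"] * n
    if coords is None:
        coords = {m: (47.0, 13.0) for m in munis}
    ids = [f"D{i:03d}" for i in range(n)]
    net = nx.Graph()
    for i, pid in enumerate(ids):
        net.add_node(pid, specialty=specialty, municipality=munis[i])
    W = np.asarray(W)
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                net.add_edge(ids[i], ids[j], weight=float(W[i, j]))
    profiles = pd.DataFrame({
        "physician_id": ids, "specialty": specialty,
        "municipality_id": munis, "opening_hours": 20.0,
        "N": np.asarray(N, dtype=int), "C": np.asarray(C, dtype=int),
    })
    gazetteer = make_municipalities(
        [(m, *coords[m]) for m in dict.fromkeys(munis)])
    return cn.compile_system(net, profiles, gazetteer)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-configuration synthetic tables plus the thresholded network."""
    cfg = cn.SynthConfig(seed=1)
    municipalities, physicians, contacts = cn.generate_dataset(cfg)
    net = cn.build_sharing_network(contacts, physicians=physicians)
    net = cn.threshold_network(net, p=2, d=100.0,
                               municipalities=municipalities)
    profiles = cn.build_profiles(contacts, physicians)
    return {"cfg": cfg, "municipalities": municipalities,
            "physicians": physicians, "contacts": contacts, "net": net,
            "profiles": profiles}


@pytest.fixture(scope="session")
def gp_stress_system():
    """A single-specialty, 200-physician system for stress scenarios."""
    cfg = cn.SynthConfig(seed=11, specialties=("GP",),
                         n_physicians_per_specialty=200, n_patients=4000,
                         visits_per_patient_mean=13.0)
    municipalities, physicians, contacts = cn.generate_dataset(cfg)
    net = cn.build_sharing_network(contacts, physicians=physicians)
    return {"cfg": cfg, "municipalities": municipalities,
            "physicians": physicians, "contacts": contacts, "net_raw": net}
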