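"""Reading and writing the pipeline's tabular interchange formats.

Everything is plain TSV (plus optional BIOM-style JSON for OTU tables and
GraphML for networks) so runs are diffable and inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import DistanceMatrix, FingerprintProfile, OTUTable

__all__ = [
    "write_otu_table",
    "read_otu_table",
    "write_otu_biom_json",
    "read_otu_biom_json",
    "write_fingerprints",
    "read_fingerprints",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_network_graphml",
]


def write_otu_table(table: OTUTable, counts_path, meta_path) -> None:
    """Counts as OTU x sample TSV with a trailing taxonomy column, plus a
    sample-metadata TSV."""
    out = table.counts.copy()
    out["taxonomy"] = table.taxonomy.values
    out.to_csv(counts_path, sep="\t", index_label="otu_id")
    table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_otu_table(counts_path, meta_path) -> OTUTable:
    df = pd.read_csv(counts_path, sep="\t", index_col="otu_id")
    taxonomy = df.pop("taxonomy")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return OTUTable(counts=df.astype(int), taxonomy=taxonomy, sample_meta=meta)


def write_otu_biom_json(table: OTUTable, path) -> None:
    """Minimal BIOM v1 (sparse, JSON) export."""
    counts = table.counts
    data = [
        [i, j, int(counts.iat[i, j])]
        for i in range(counts.shape[0])
        for j in range(counts.shape[1])
        if counts.iat[i, j]
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "weanling",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(counts.shape),
        "rows": [
            {"id": o, "metadata": {"taxonomy": table.taxonomy.get(o)}}
            for o in counts.index
        ],
        "columns": [
            {"id": s, "metadata": table.sample_meta.loc[s].to_dict()}
            for s in counts.columns
        ],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


def read_otu_biom_json(path) -> OTUTable:
    doc = json.loads(Path(path).read_text())
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    counts = pd.DataFrame(0, index=otus, columns=samples, dtype=int)
    for i, j, v in doc["data"]:
        counts.iat[i, j] = v
    taxonomy = pd.Series(
        {r["id"]: (r.get("metadata") or {}).get("taxonomy") for r in doc["rows"]}
    )
    meta = pd.DataFrame(
        [(c.get("metadata") or {}) for c in doc["columns"]], index=samples
    )
    return OTUTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


def write_fingerprints(profiles: dict[str, FingerprintProfile], outdir) -> None:
    """One two-column TSV per trace plus a manifest and size-standard TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sid, prof in profiles.items():
        path = outdir / f"{sid}.trace.tsv"
        pd.DataFrame({"position": prof.positions, "intensity": prof.intensities}).to_csv(
            path, sep="\t", index=False
        )
        for obs, nom in prof.standard_peaks:
            manifest.append({"sample": sid, "file": path.name,
                             "observed": obs, "nominal": nom})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.tsv", sep="\t", index=False)


def read_fingerprints(outdir) -> dict[str, FingerprintProfile]:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t")
    profiles = {}
    for (sid, fname), sub in manifest.groupby(["sample", "file"]):
        df = pd.read_csv(outdir / fname, sep="\t")
        profiles[sid] = FingerprintProfile(
            sample_id=sid,
            positions=df["position"].values,
            intensities=df["intensity"].values,
            standard_peaks=list(zip(sub["observed"], sub["nominal"])),
        )
    return profiles


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep="\t", index_label="sample")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return DistanceMatrix.from_frame(df)


def write_network_graphml(edges: pd.DataFrame, path) -> None:
    """Edge list (source, target, similarity, sign) as GraphML."""
    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_edge(e["source"], e["target"],
                   similarity=float(e["similarity"]), sign=str(e["sign"]))
    nx.write_graphml(g, path)
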