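"""Figures, result tables and the end-to-end pipeline.

The circos-style summary places every kept position on a circle with, from
the outside in: residue labels, conservation color boxes (red = most
conserved, cyan = least), the cMI histogram facing outward, the pMI
histogram facing inward, and chords in the center connecting significantly
coevolving pairs colored by percentile band (red top 5%, black 70-95%, gray
rest).
"""

from __future__ import annotations

import json
import logging
import math
import time
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.path import Path as MplPath
from matplotlib.patches import PathPatch, Wedge

import coevomap
from coevomap import msa_io, weighting, mi_engine, conservation as conservation_mod
from coevomap import structure_map, coevo_network
from coevomap.coevo_network import BAND_TOP, BAND_MID, BAND_LOW

logger = logging.getLogger(__name__)

# red = most conserved, cyan = least (circos ring 2 and network node colors)
CONSERVATION_CMAP = LinearSegmentedColormap.from_list("kl_red_cyan", ["cyan", "red"])

BAND_COLORS = {BAND_TOP: "red", BAND_MID: "black", BAND_LOW: "0.7"}

_SECONDARY_COLORS = {"helix": "tab:red", "sheet": "tab:blue", "coil": "0.7", None: "0.7"}

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class CircosLayout:
    """Radii and style of the circular summary tracks (outer to inner)."""

    label_radius: float = 1.36
    conservation_inner: float = 1.20
    conservation_outer: float = 1.28
    cmi_base: float = 1.00
    cmi_max_height: float = 0.17
    pmi_base: float = 0.97
    pmi_max_depth: float = 0.17
    chord_radius: float = 0.76


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    msa: str
    out_dir: str
    format: str = "auto"
    reference: str | None = None
    pdb: str | None = None
    chain: str | None = None
    identity_threshold: float = 0.62
    pseudocount: float = 0.05
    n_permutations: int = 100
    seed: int = mi_engine.DEFAULT_SEED
    max_gap_fraction: float = 0.5
    z_threshold: float = 6.5
    distance_cutoff: float = 5.0
    null: str = "per-pair"
    background: str = "blosum62"


def _node_order(network: nx.Graph) -> list[int]:
    return sorted(network.nodes)


def _node_label(network: nx.Graph, node: int) -> str:
    data = network.nodes[node]
    number = data.get("pdb_number") or str(node)
    return f"{data.get('aa', 'X')}{number}"


def render_circos(
    network: nx.Graph,
    out: str | Path,
    layout: CircosLayout | None = None,
) -> dict[str, Path]:
    """Render the circular summary; writes both SVG and PNG next to ``out``.

    Every kept position appears once in sequence order. Returns the paths of
    the written files.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot render a circos with zero positions")
    layout = layout or CircosLayout()
    order = _node_order(network)
    k = len(order)
    theta = {node: 2 * math.pi * idx / k for idx, node in enumerate(order)}

    kl = np.array([network.nodes[n]["kl"] for n in order], dtype=float)
    cmi = np.array([network.nodes[n]["cmi"] for n in order], dtype=float)
    pmi = np.array([network.nodes[n]["pmi"] for n in order], dtype=float)

    with plt.rc_context({"svg.hashsalt": "coevomap"}):
        fig, ax = plt.subplots(figsize=(9, 9))
        ax.set_aspect("equal")
        ax.axis("off")
        lim = layout.label_radius + 0.22
        ax.set_xlim(-lim, lim)
        ax.set_ylim(-lim, lim)

        # ring 1: labels
        for node in order:
            ang = theta[node]
            deg = math.degrees(ang)
            rot = deg if -90 <= ((deg + 90) % 360) - 90 <= 90 else deg + 180
            txt = ax.text(
                layout.label_radius * math.cos(ang),
                layout.label_radius * math.sin(ang),
                _node_label(network, node),
                rotation=deg - 90 if 0 <= deg <= 180 else deg + 90,
                ha="center", va="center", fontsize=max(3, min(9, 400 / k)),
            )
            txt.set_gid(f"circos-label-{node}")

        # ring 2: conservation boxes
        finite_kl = kl[np.isfinite(kl)]
        norm = Normalize(vmin=finite_kl.min() if finite_kl.size else 0.0,
                         vmax=finite_kl.max() if finite_kl.size else 1.0)
        half = 0.85 * 180.0 / k  # half-width in degrees
        for idx, node in enumerate(order):
            deg = math.degrees(theta[node])
            color = CONSERVATION_CMAP(norm(kl[idx])) if np.isfinite(kl[idx]) else "0.9"
            wedge = Wedge((0, 0), layout.conservation_outer, deg - half, deg + half,
                          width=layout.conservation_outer - layout.conservation_inner,
                          facecolor=color, edgecolor="none")
            wedge.set_gid(f"circos-conservation-{node}")
            ax.add_patch(wedge)

        # rings 3 & 4: cMI outward, pMI inward, each scaled to its own max
        def bars(values, base, extent, outward, tag):
            finite = values[np.isfinite(values)]
            vmax = finite.max() if finite.size and finite.max() > 0 else 1.0
            for idx, node in enumerate(order):
                v = values[idx]
                if not np.isfinite(v) or v <= 0:
                    continue
                h = extent * v / vmax
                deg = math.degrees(theta[node])
                r_out = base + h if outward else base
                w = h if outward else h
                wedge = Wedge((0, 0), r_out, deg - half, deg + half, width=w,
                              facecolor="tab:orange" if outward else "tab:purple",
                              edgecolor="none")
                wedge.set_gid(f"circos-{tag}-{node}")
                ax.add_patch(wedge)

        bars(cmi, layout.cmi_base, layout.cmi_max_height, True, "cmi")
        bars(pmi, layout.pmi_base, layout.pmi_max_depth, False, "pmi")

        # center: chords colored by percentile band
        r = layout.chord_radius
        for u, v, data in network.edges(data=True):
            p1 = (r * math.cos(theta[u]), r * math.sin(theta[u]))
            p2 = (r * math.cos(theta[v]), r * math.sin(theta[v]))
            path = MplPath([p1, (0.0, 0.0), p2],
                           [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
            patch = PathPatch(path, fill=False, lw=0.9,
                              edgecolor=BAND_COLORS.get(data.get("band"), "0.7"),
                              alpha=0.9)
            patch.set_gid(f"circos-chord-{u}-{v}")
            ax.add_patch(patch)

        out = Path(out)
        stem = out.with_suffix("")
        svg_path, png_path = stem.with_suffix(".svg"), stem.with_suffix(".png")
        fig.savefig(svg_path, metadata={"Date": None})
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return {"svg": svg_path, "png": png_path}


_NODE_COLOR_ATTRS = {"conservation": "kl", "kl": "kl", "cmi": "cmi", "pmi": "pmi",
                     "secondary": "secondary"}


def _node_colors(network: nx.Graph, attribute: str, order: list[int]):
    if attribute not in _NODE_COLOR_ATTRS:
        raise ValueError(
            f"unknown node color attribute {attribute!r}; "
            f"choose from {sorted(set(_NODE_COLOR_ATTRS))}"
        )
    attr = _NODE_COLOR_ATTRS[attribute]
    if attr == "secondary":
        return [_SECONDARY_COLORS.get(network.nodes[n]["secondary"], "0.7")
                for n in order]
    vals = np.array([network.nodes[n][attr] for n in order], dtype=float)
    finite = vals[np.isfinite(vals)]
    norm = Normalize(vmin=finite.min() if finite.size else 0,
                     vmax=finite.max() if finite.size else 1)
    return [CONSERVATION_CMAP(norm(v)) if np.isfinite(v) else (0.9, 0.9, 0.9, 1.0)
            for v in vals]


def render_networks(
    network: nx.Graph,
    out_dir: str | Path,
    distance_net: nx.Graph | None = None,
    color_by: str = "conservation",
    layout_seed: int = 0,
) -> dict[str, Path]:
    """Static MI-network image (and distance-network image if provided).

    Node color follows the selected attribute through the red-cyan scale
    (red = highest). The force-directed layout is seeded for determinism.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def draw(graph: nx.Graph, name: str, labels: bool) -> Path:
        pos = nx.spring_layout(graph, seed=layout_seed)
        fig, ax = plt.subplots(figsize=(8, 8))
        ax.axis("off")
        colors = _node_colors(graph, color_by, list(graph.nodes)) if labels else "0.6"
        nx.draw_networkx_edges(graph, pos, ax=ax, edge_color="0.6", width=0.8)
        nx.draw_networkx_nodes(graph, pos, ax=ax, node_color=colors, node_size=120)
        if labels:
            nx.draw_networkx_labels(
                graph, pos, {n: _node_label(graph, n) for n in graph.nodes},
                font_size=6, ax=ax)
        path = out_dir / name
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path

    written["mi_network"] = draw(network, "mi_network.png", labels=True)
    if distance_net is not None:
        written["distance_network"] = draw(distance_net, "distance_network.png",
                                           labels=False)
    return written


# ---------------------------------------------------------------------------
# tables and network files

def node_table(network: nx.Graph) -> pd.DataFrame:
    rows = []
    for node in _node_order(network):
        d = network.nodes[node]
        rows.append({
            "position": node,
            "aa": d.get("aa", "X"),
            "pdb_number": d.get("pdb_number") or "",
            "kl": d.get("kl", math.nan),
            "cmi": d.get("cmi", 0.0),
            "pmi": d.get("pmi", math.nan),
            "secondary": d.get("secondary") or "",
        })
    return pd.DataFrame(rows)


def edge_table(network: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in sorted(network.edges(data=True)):
        a, b = (u, v) if u <= v else (v, u)
        rows.append({
            "position_i": a,
            "position_j": b,
            "z": d["z"],
            "band": d.get("band") or "",
            "distance_A": d.get("distance", math.nan),
            "separation": d.get("separation", abs(a - b)),
        })
    df = pd.DataFrame(rows, columns=["position_i", "position_j", "z", "band",
                                     "distance_A", "separation"])
    return df.sort_values(["position_i", "position_j"]).reset_index(drop=True)


def write_sif(network: nx.Graph, path: str | Path, relation: str = "mi") -> None:
    """Cytoscape SIF: one line per edge; isolated nodes on their own lines."""
    with open(path, "w") as fh:
        isolated = [n for n in _node_order(network) if network.degree(n) == 0]
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def network_from_tables(nodes: pd.DataFrame, edges: pd.DataFrame) -> nx.Graph:
    """Rebuild a coevolution network from saved node and edge tables."""
    graph = nx.Graph()
    for _, row in nodes.iterrows():
        graph.add_node(
            int(row["position"]),
            kept_index=-1,
            aa=row["aa"],
            pdb_number=(str(row["pdb_number"]) if str(row.get("pdb_number", "")) else None),
            kl=float(row["kl"]),
            cmi=float(row["cmi"]),
            pmi=float(row["pmi"]) if pd.notna(row["pmi"]) else math.nan,
            secondary=(row["secondary"] if str(row.get("secondary", "")) else None),
        )
    for _, row in edges.iterrows():
        graph.add_edge(
            int(row["position_i"]), int(row["position_j"]),
            z=float(row["z"]),
            band=row["band"] if str(row.get("band", "")) else None,
            distance=float(row["distance_A"]) if pd.notna(row["distance_A"]) else math.nan,
            separation=int(row["separation"]),
        )
    return graph


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def bundle_results(out_dir: str | Path, zip_name: str = "results_bundle.zip",
                   expected: list[str] | None = None) -> Path:
    """Zip every artifact in ``out_dir``; the manifest records present/missing items."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    present = sorted(p.name for p in out_dir.iterdir()
                     if p.is_file() and p.name != zip_name)
    if expected:
        manifest["artifacts"] = {name: name in present for name in expected}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        present = sorted(set(present) | {"manifest.json"})
    zip_path = out_dir / zip_name
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in present:
            zf.write(out_dir / name, arcname=name)
    return zip_path


_EXPECTED_ARTIFACTS = [
    "msa_processed.fasta", "weights.tsv", "zscores_raw.tsv", "edges.tsv",
    "nodes.tsv", "conservation.tsv", "logo_matrix.tsv", "network.sif",
    "circos.svg", "circos.png", "mi_network.png",
    "distance_network.sif", "distance_network.png",
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis: MSA -> weights -> MI z-scores -> conservation ->
    (structure) -> network -> figures and bundle.

    Returns a dict with the network, score matrices and artifact paths. Any
    stage failure is re-raised annotated with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return _Stage()

    with stage("msa_io"):
        alignment = msa_io.read_msa(config.msa, config.format)
        alignment = msa_io.set_reference(alignment, config.reference)
        mask = msa_io.mask_columns(alignment, config.max_gap_fraction)
        counts["n_sequences"] = alignment.n_sequences
        counts["n_kept_columns"] = mask.n_kept
        msa_io.write_fasta(alignment, out_dir / "msa_processed.fasta")

    with stage("weighting"):
        weights = weighting.cluster_weights(alignment, config.identity_threshold)
        counts["n_clusters"] = weights.n_clusters
        _write_tsv(pd.DataFrame({"identifier": alignment.identifiers,
                                 "weight": weights.weight}),
                   out_dir / "weights.tsv")

    with stage("mi_engine"):
        scores = mi_engine.permutation_zscores(
            alignment, mask, weights,
            pseudocount=config.pseudocount,
            n_permutations=config.n_permutations,
            seed=config.seed,
            null=config.null,
        )

    with stage("conservation"):
        bg = (conservation_mod.uniform_background() if config.background == "uniform"
              else conservation_mod.blosum62_background())
        profile = conservation_mod.kl_conservation(
            alignment, mask, weights, background=bg, pseudocount=config.pseudocount)
        _write_tsv(pd.DataFrame({"position": profile.positions, "kl": profile.kl}),
                   out_dir / "conservation.tsv")
        logo = conservation_mod.logo_data(
            alignment, mask, weights, columns=mask.kept_columns,
            background=bg, pseudocount=config.pseudocount)
        logo.reset_index().to_csv(out_dir / "logo_matrix.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FMT, na_rep="NA")

    structure = seqstruct = distances = dist_net = None
    if config.pdb:
        with stage("structure_map"):
            structure = structure_map.read_structure(config.pdb, config.chain)
            distances = structure_map.min_distances(structure)
            seqstruct = structure_map.map_alignment_to_structure(alignment, mask, structure)
            dist_net = structure_map.distance_network(distances, config.distance_cutoff)
            counts["structure_residues"] = structure.n_residues
            counts["mapping_coverage"] = round(seqstruct.coverage, 4)

    with stage("coevo_network"):
        kept = mask.kept_columns
        ref_aa = [alignment.reference_sequence[c] for c in kept]
        network = coevo_network.build_network(
            scores, threshold=config.z_threshold,
            conservation=profile.kl, reference_aa=ref_aa)
        if structure is not None:
            coevo_network.proximity_mi(network, seqstruct, distances,
                                       radius=config.distance_cutoff)
            # secondary labels for mapped nodes
            for node, data in network.nodes(data=True):
                ridx = seqstruct.column_to_residue.get(data["kept_index"])
                if ridx is not None:
                    data["secondary"] = structure.secondary[ridx]
        counts["n_edges"] = network.number_of_edges()

    with stage("reporting"):
        edges_df = edge_table(network)
        _write_tsv(edges_df, out_dir / "edges.tsv")
        _write_tsv(node_table(network), out_dir / "nodes.tsv")
        _write_tsv(edges_df[["position_i", "position_j", "z"]],
                   out_dir / "zscores_raw.tsv")
        write_sif(network, out_dir / "network.sif")
        circos_paths = render_circos(network, out_dir / "circos.svg")
        image_paths = render_networks(network, out_dir, distance_net=dist_net)
        if dist_net is not None and structure is not None:
            relabeled = nx.relabel_nodes(
                dist_net, {i: structure.residues[i].author_number
                           for i in dist_net.nodes})
            write_sif(relabeled, out_dir / "distance_network.sif", relation="contact")

        manifest = {
            "package": "coevomap",
            "version": coevomap.__version__,
            "parameters": asdict(config),
            "seed": config.seed,
            "timings_s": timings,
            "counts": counts,
            "artifacts": {name: (out_dir / name).exists()
                          for name in _EXPECTED_ARTIFACTS},
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        zip_path = bundle_results(out_dir, expected=_EXPECTED_ARTIFACTS)

    return {
        "alignment": alignment,
        "mask": mask,
        "weights": weights,
        "scores": scores,
        "conservation": profile,
        "network": network,
        "distance_network": dist_net,
        "structure": structure,
        "seqstruct_map": seqstruct,
        "out_dir": out_dir,
        "bundle": zip_path,
        "circos": circos_paths,
        "images": image_paths,
        "manifest": manifest,
    }
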