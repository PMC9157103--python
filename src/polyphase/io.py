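"""Readers and writers for the pipeline's plain-text formats.

Pillar file (TSV): one row per pillar with columns

    pillar_id, then per genome G: G_t0..G_t{N-1} (gene id or "-" for an
    absent copy) and G_adj (1 = synteny maintained to the previous pillar,
    0 = break), plus optional G_nhom columns (outgroup homolog counts).

Trees are Newick with branch lengths on the expected-loss (alpha*t) scale
and the root branch encoded as the root edge length.  Ks and
conversion-likelihood tables are TSV via pandas; essentiality and veto
lists are one gene id per line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .orthology_hmm import Pillar, SpeciesTree

__all__ = [
    "write_pillars",
    "read_pillars",
    "write_tree",
    "read_tree",
    "write_table",
    "read_table",
    "write_gene_list",
    "read_gene_list",
    "write_model_spec",
    "read_model_spec",
    "write_bundle",
    "read_bundle",
]

ABSENT = "-"


def write_pillars(pillars: list[Pillar], path, genomes: list[str] | None = None) -> None:
    path = Path(path)
    if genomes is None:
        genomes = sorted(pillars[0].genes)
    ploidy = len(pillars[0].genes[genomes[0]])
    with_counts = any(p.homolog_counts for p in pillars)
    cols = ["pillar_id"]
    for g in genomes:
        cols += [f"{g}_t{j}" for j in range(ploidy)] + [f"{g}_adj"]
        if with_counts:
            cols.append(f"{g}_nhom")
    rows = []
    for p in pillars:
        row = [p.pillar_id]
        for g in genomes:
            row += [x if x is not None else ABSENT for x in p.genes[g]]
            row.append(1 if p.adjacency.get(g, True) else 0)
            if with_counts:
                row.append((p.homolog_counts or {}).get(g, ""))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_pillars(path) -> tuple[list[Pillar], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    genomes = [c[:-4] for c in df.columns if c.endswith("_adj")]
    ploidy = max(int(c.rsplit("_t", 1)[1]) for c in df.columns if "_t" in c
                 and c.rsplit("_t", 1)[0] in genomes) + 1
    with_counts = any(c.endswith("_nhom") for c in df.columns)
    pillars = []
    for _, row in df.iterrows():
        genes = {}
        adj = {}
        counts = {}
        for g in genomes:
            genes[g] = tuple(
                None if row[f"{g}_t{j}"] == ABSENT else row[f"{g}_t{j}"]
                for j in range(ploidy))
            adj[g] = bool(int(row[f"{g}_adj"]))
            if with_counts and row.get(f"{g}_nhom") not in (None, "", "nan"):
                counts[g] = int(float(row[f"{g}_nhom"]))
        pillars.append(Pillar(row["pillar_id"], genes, adj,
                              counts if counts else None))
    return pillars, genomes


def write_tree(tree: SpeciesTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_tree(path) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text())


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


_SPEC_TYPES = None


def _spec_types():
    global _SPEC_TYPES
    if _SPEC_TYPES is None:
        from .loss_models import WGDModelSpec, WGTModelSpec, WGQModelSpec

        _SPEC_TYPES = {"wgd": WGDModelSpec, "wgt": WGTModelSpec,
                       "wgq": WGQModelSpec}
    return _SPEC_TYPES


def write_model_spec(spec, path) -> None:
    """Serialize a loss-model spec as a flat key-value YAML mapping."""
    family = {v: k for k, v in _spec_types().items()}[type(spec)]
    payload = {"family": family}
    for k, v in vars(spec).items():
        if v is None or isinstance(v, (int, float, bool, str)):
            payload[k] = v
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_model_spec(path):
    payload = yaml.safe_load(Path(path).read_text())
    family = payload.pop("family")
    try:
        cls = _spec_types()[family]
    except KeyError:
        raise ValueError(f"unknown model family {family!r}") from None
    return cls(**payload)


def write_bundle(bundle: dict, out_dir) -> None:
    """Write a synthetic dataset bundle (see
    :func:`polyphase.synthetic_data.generate_dataset`) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = bundle["tree"].leaves
    write_pillars(bundle["pillars"], out / "pillars.tsv", genomes)
    write_tree(bundle["tree"], out / "tree.nwk")
    write_table(bundle["ks"], out / "ks.tsv")
    write_table(bundle["conversion"], out / "conversion_lnl.tsv")
    truth = bundle["truth"]
    write_gene_list(sorted(g for g, e in truth.essentiality.items() if e),
                    out / "essential_genes.txt")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.DataFrame({
        "pillar_id": [p.pillar_id for p in bundle["pillars"]],
        "phasing_state": truth.phasing_states,
    }).to_csv(truth_dir / "phasing.tsv", sep="\t", index=False)
    np.savetxt(truth_dir / "break_flags.tsv", truth.break_flags.astype(int),
               fmt="%d", delimiter="\t")
    np.savetxt(truth_dir / "node_states.tsv", truth.node_states,
               fmt="%d", delimiter="\t")
    rgl_rows = [(a, b, pid) for (a, b), pids in truth.rgl_truth.items()
                for pid in pids]
    pd.DataFrame(rgl_rows, columns=["genome_a", "genome_b", "pillar_id"]).to_csv(
        truth_dir / "rgl_truth.tsv", sep="\t", index=False)
    cfg = bundle["config"]
    manifest = {
        "seed": cfg.seed, "n_taxa": cfg.n_taxa, "m": cfg.m,
        "theta": cfg.theta, "break_prob": cfg.break_prob,
        "model": type(cfg.model).__name__,
        "model_params": {k: v for k, v in vars(cfg.model).items()
                         if isinstance(v, (int, float, bool))},
        "tree": bundle["tree"].to_newick(),
        "dropped_resims": truth.dropped_resims,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_bundle(out_dir) -> dict:
    out = Path(out_dir)
    pillars, genomes = read_pillars(out / "pillars.tsv")
    return {
        "pillars": pillars,
        "genomes": genomes,
        "tree": read_tree(out / "tree.nwk"),
        "ks": read_table(out / "ks.tsv"),
        "conversion": read_table(out / "conversion_lnl.tsv"),
        "essential": read_gene_list(out / "essential_genes.txt"),
        "manifest": yaml.safe_load((out / "manifest.yaml").read_text()),
    }
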