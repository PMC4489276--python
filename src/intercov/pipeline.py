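"""End-to-end orchestration: paired MSA -> scores -> comparison -> figures.

``run_pipeline`` is the library entry point behind the ``intercov run``
command. All products are plain text (FASTA, TSV, JSON, SVG) plus optional
PNG figures, and a manifest records parameters, seeds and the produced
files, so a rerun with the same inputs and seed reproduces the score TSVs
byte for byte.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .compare import (ScoreTable, density_summary, export_scores,
                      import_external_scores, rank_pairs, top_overlap,
                      write_json)
from .dca import (direct_information, frobenius_apc_score, mfdca_fit,
                  plmdca_fit, reweight_sequences)
from .mi import mi_zscores, position_conservation, weighted_frequencies
from .msa import (cluster_weights, hobohm1, read_fasta_msa,
                  write_cluster_report)
from .pairing import (best_hit_per_taxid, build_paired_msa, read_hit_table,
                      validate_user_paired_msas, write_paired_msa)
from .plots import render_circos, render_matrix, save_figure

KNOWN_METHODS = ("mi", "mfdca", "plmdca", "external")


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Exactly one input mode is used: per-protein hit tables plus a
    references FASTA (automatic pairing), or per-protein pre-paired MSAs
    (validated and concatenated).
    """

    out_dir: str
    methods: list[str] = dc_field(default_factory=lambda: ["mi"])
    # automatic-pairing mode
    hit_tables: list[str] = dc_field(default_factory=list)
    references_fasta: str | None = None
    # user-MSA mode
    msa_paths: list[str] = dc_field(default_factory=list)
    taxid_pattern: str | None = None
    labels: list[str] | None = None
    external_scores: list[str] = dc_field(default_factory=list)
    seed: int = 0
    identity_threshold: float = 0.62
    mi_pseudocount: float = 0.05
    mi_replicates: int = 100
    dca_theta: float = 0.8
    mf_pseudocount: float = 0.5
    plm_lambda_h: float = 0.01
    plm_lambda_e: float | None = None
    min_coverage: float = 0.5
    top_n: int = 25
    overlap_class: str = "inter"
    make_figures: bool = True

    def __post_init__(self):
        if not self.methods:
            raise ValueError("methods must be non-empty")
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}; known: "
                                 f"{KNOWN_METHODS}")
        if "external" in self.methods and not self.external_scores:
            raise ValueError("method 'external' requires external score "
                             "files")


def _build_paired(config: RunConfig):
    if config.msa_paths:
        msas = [read_fasta_msa(p, config.taxid_pattern)
                for p in config.msa_paths]
        return validate_user_paired_msas(msas, config.labels,
                                         config.min_coverage)
    if not config.hit_tables or not config.references_fasta:
        raise ValueError("either msa_paths or hit_tables + references_fasta "
                         "must be given")
    from Bio import SeqIO
    from .alphabet import normalize_residues
    from .msa import SequenceRecord
    refs = [SequenceRecord(r.id, normalize_residues(str(r.seq)))
            for r in SeqIO.parse(str(config.references_fasta), "fasta")]
    if len(refs) != len(config.hit_tables):
        raise ValueError("one reference per hit table required")
    per_protein = []
    for k, (ref, path) in enumerate(zip(refs, config.hit_tables)):
        hits = read_hit_table(path, query_index=k)
        per_protein.append((ref, best_hit_per_taxid(hits)))
    return build_paired_msa(per_protein, config.labels, config.min_coverage)


def run_pipeline(config: RunConfig) -> Path:
    """Run pairing, scoring, comparison and reporting; returns the output
    directory. Partial outputs are kept (with the failure recorded in the
    manifest) when a stage raises."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "intercov",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items()
                       if k != "out_dir"},
        "files": [],
        "status": "running",
    }
    try:
        _run_stages(config, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["traceback"] = traceback.format_exc()
        write_json(manifest, out / "manifest.json")
        raise
    write_json(manifest, out / "manifest.json")
    return out


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    paired = _build_paired(config)
    write_paired_msa(paired, out / "paired_msa.fasta", out / "segments.tsv")
    manifest["files"] += ["paired_msa.fasta", "segments.tsv"]
    msa = paired.msa
    reference = msa.reference.residues

    clusters = hobohm1(msa, config.identity_threshold)
    weights = cluster_weights(clusters)
    write_cluster_report(msa, clusters, weights, out / "clusters.tsv")
    manifest["files"].append("clusters.tsv")
    manifest["alignment"] = {"n_sequences": msa.n_records,
                             "n_columns": msa.length,
                             "n_clusters": clusters.n_clusters}

    freqs = weighted_frequencies(msa, weights, config.mi_pseudocount)
    conservation = position_conservation(freqs)
    np.savetxt(out / "conservation.tsv",
               np.column_stack([np.arange(1, msa.length + 1), conservation]),
               fmt=("%d", "%.6g"), delimiter="\t",
               header="position\tconservation_kl", comments="")
    manifest["files"].append("conservation.tsv")

    tables: dict[str, ScoreTable] = {}
    if "mi" in config.methods:
        mimat, null = mi_zscores(msa, weights, config.mi_pseudocount,
                                 config.mi_replicates, config.seed)
        table = ScoreTable("zscore", mimat.zscore, paired.segments)
        export_scores(table, out / "mi.tsv", reference,
                      extra={"raw_mi": mimat.raw_mi, "mip": mimat.mip})
        manifest["files"].append("mi.tsv")
        manifest["mi_null"] = {"mean": null.null_mean, "sd": null.null_sd,
                               "n_replicates": null.n_replicates}
        tables["mi"] = table
    dca_weights = None
    if "mfdca" in config.methods or "plmdca" in config.methods:
        dca_weights = reweight_sequences(msa, config.dca_theta)
        manifest["dca_meff"] = dca_weights.meff
    if "mfdca" in config.methods:
        model = mfdca_fit(msa, dca_weights, config.mf_pseudocount)
        di = direct_information(model)
        table = ScoreTable("di", di, paired.segments)
        export_scores(table, out / "mfdca.tsv", reference,
                      extra={"fapc": frobenius_apc_score(model)})
        manifest["files"].append("mfdca.tsv")
        tables["mfdca"] = table
    if "plmdca" in config.methods:
        model = plmdca_fit(msa, dca_weights, config.plm_lambda_h,
                           config.plm_lambda_e)
        fapc = frobenius_apc_score(model)
        table = ScoreTable("fapc", fapc, paired.segments)
        export_scores(table, out / "plmdca.tsv", reference)
        manifest["files"].append("plmdca.tsv")
        manifest["plmdca_converged"] = model.converged
        tables["plmdca"] = table
    if "external" in config.methods:
        for k, path in enumerate(config.external_scores):
            table = import_external_scores(path, paired.segments, msa.length)
            name = table.method if table.method != "external" \
                else f"external{k + 1}"
            tables[name] = table

    densities = {name: density_summary(t) for name, t in tables.items()}
    write_json(densities, out / "density.json")
    manifest["files"].append("density.json")

    ranked = {name: rank_pairs(t) for name, t in tables.items()}
    if len(ranked) >= 2:
        try:
            overlap = top_overlap(dict(list(ranked.items())[:4]),
                                  config.overlap_class, config.top_n)
            write_json(overlap, out / "overlap.json")
            manifest["files"].append("overlap.json")
        except ValueError as exc:
            manifest["overlap_skipped"] = str(exc)

    if config.make_figures:
        from .compare import _class_matches
        for name, table in tables.items():
            avail = int(ranked[name]["cls"].map(
                lambda c: _class_matches(c, config.overlap_class)).sum())
            if avail == 0:
                continue
            svg = render_circos(table, conservation,
                                {"class": config.overlap_class,
                                 "n": min(config.top_n, avail)},
                                reference)
            (out / f"circos_{name}.svg").write_text(svg)
            ax = render_matrix(table)
            save_figure(ax, out / f"matrix_{name}.png")
            import matplotlib.pyplot as plt
            plt.close(ax.figure)
            manifest["files"] += [f"circos_{name}.svg", f"matrix_{name}.png"]
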