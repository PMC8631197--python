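"""End-to-end orchestration: simulate/load -> normalize -> DE -> scan ->
ceRNA networks -> enrichment, with a reproducible output bundle.

Every stage writes plain-text outputs under the configured directory and
logs one structured line (stage, input size, surviving size, elapsed).
The run manifest records the configuration, the seed, the package version
and a SHA-256 over the configuration and all deterministic outputs; a
repeat run with the same config and seed reproduces the hash bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as cio
from .cerna import (assemble_network, export_network, intersect_hub_mrnas,
                    network_summary)
from .config import PipelineConfig
from .containers import RNA_CLASSES
from .enrich import gsea_batch, ora_batch
from .expression import (call_de, fpkm, nb_wald_test, size_factors,
                         size_factors_from_totals, srpbm, tpm)
from .mre import build_target_table
from .simulate import read_fixture, simulate_experiment, write_fixture

log = logging.getLogger("cernapipe")

TARGET_CLASSES = ("mRNA", "lncRNA", "circRNA")


@dataclass
class ResultBundle:
    """Everything one pipeline run produced."""

    outdir: Path
    de: dict[str, pd.DataFrame]
    de_counts: dict[str, dict]
    pairs: pd.DataFrame
    networks: dict[str, nx.Graph]
    summaries: dict[str, dict]
    hub_mrnas: list[str]
    ora: pd.DataFrame | None
    gsea: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _stage(name: str, n_in, n_out, t0: float) -> None:
    log.info("stage=%s in=%s out=%s elapsed=%.2fs",
             name, n_in, n_out, time.time() - t0)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every stage in order; same config + seed => identical bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    th = config.thresholds
    try:
        # ---- stage: input -------------------------------------------------
        t0 = time.time()
        if config.sim is not None:
            dataset = simulate_experiment(config.sim)
            fixture_dir = outdir / "fixture"
            write_fixture(dataset, fixture_dir)
            # read back through the package's own readers: the pipeline
            # consumes only what its formats can carry
            dataset = read_fixture(fixture_dir)
        else:
            dataset = read_fixture(config.input_dir)
        n_feat = {c: dataset.counts[c].n_features for c in RNA_CLASSES}
        _stage("input", "-", n_feat, t0)

        # ---- stage: normalize --------------------------------------------
        t0 = time.time()
        expr = {
            "mRNA": fpkm(dataset.counts["mRNA"]).values,
            "lncRNA": fpkm(dataset.counts["lncRNA"]).values,
            "miRNA": tpm(dataset.counts["miRNA"]).values,
            "circRNA": srpbm(dataset.counts["circRNA"],
                             dataset.mapped_reads).values,
        }
        for cls, df in expr.items():
            df.rename_axis("feature_id").reset_index().to_csv(
                outdir / f"expr_{cls}.tsv", sep="\t", index=False,
                float_format="%.10g")
        _stage("normalize", sum(n_feat.values()), sum(n_feat.values()), t0)

        # ---- stage: differential expression ------------------------------
        t0 = time.time()
        reference = dataset.groups.iloc[0]
        de: dict[str, pd.DataFrame] = {}
        de_counts: dict[str, dict] = {}
        # The correlation stage runs on median-of-ratios-normalized counts
        # rather than the per-sum units above: per-sum normalizations pass
        # composition shifts between conditions into every feature's
        # profile, which attenuates the |r| > 0.9 signals the sponge
        # filters depend on.
        corr_expr: dict[str, pd.DataFrame] = {}
        for cls in RNA_CLASSES:
            cm = dataset.counts[cls]
            sf = size_factors_from_totals(dataset.mapped_reads) \
                if cls == "circRNA" else size_factors(cm)
            corr_expr[cls] = cm.values.div(sf, axis=1)
            res = nb_wald_test(cm, dataset.groups, reference=reference, sf=sf)
            table, counts = call_de(res, th.lfc_cut, th.padj_cut)
            table.insert(0, "feature_class", cls)
            de[cls] = table
            de_counts[cls] = counts
            cio.write_de_table(table, outdir / f"de_{cls}.tsv")
        _stage("de", sum(n_feat.values()),
               {c: de_counts[c]["total"] for c in RNA_CLASSES}, t0)

        # ---- stage: MRE scan ----------------------------------------------
        t0 = time.time()
        mirna_seqs = {i: dataset.sequences[i]
                      for i in dataset.counts["miRNA"].values.index
                      if i in dataset.sequences}
        target_seqs = {i: dataset.sequences[i]
                       for cls in TARGET_CLASSES
                       for i in dataset.counts[cls].values.index
                       if i in dataset.sequences}
        pairs = build_target_table(mirna_seqs, target_seqs,
                                   min_class=th.min_class,
                                   min_score=th.min_score)
        pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        _stage("scan", f"{len(mirna_seqs)}x{len(target_seqs)}", len(pairs), t0)

        # ---- stage: ceRNA networks ----------------------------------------
        networks: dict[str, nx.Graph] = {}
        summaries: dict[str, dict] = {}
        for label, ce_class in (("DMLCN", "lncRNA"), ("DMCCN", "circRNA")):
            t0 = time.time()
            net = assemble_network(de, pairs, corr_expr, ce_class, th)
            networks[label] = net
            summaries[label] = network_summary(net)
            base = outdir / label.lower()
            export_network(net, base, "tsv")
            export_network(net, base.with_suffix(".sif"), "sif")
            export_network(net, base.with_suffix(".graphml"), "graphml")
            _stage(f"cerna_{label}", de_counts[ce_class]["total"],
                   summaries[label]["n_edges"], t0)
        hubs = intersect_hub_mrnas(networks["DMLCN"], networks["DMCCN"])
        (outdir / "hub_mrnas.txt").write_text("".join(h + "\n" for h in hubs))
        with open(outdir / "summary.json", "w") as fhj:
            json.dump({"de_counts": de_counts, "networks": summaries,
                       "hub_mrnas": hubs}, fhj, indent=2, sort_keys=True)

        # ---- stage: enrichment --------------------------------------------
        t0 = time.time()
        ora = gsea = None
        gmt_path = (Path(config.input_dir) if config.input_dir
                    else outdir / "fixture") / "gene_sets.gmt"
        if gmt_path.exists():
            gene_sets = cio.read_gmt(gmt_path)
            study = sorted(de["mRNA"].index[de["mRNA"]["direction"] != "ns"])
            population = sorted(de["mRNA"].index)
            ora = ora_batch(study, population, gene_sets)
            ora.to_csv(outdir / "ora.tsv", sep="\t", index=False,
                       float_format="%.10g")
            gsea = gsea_batch(de["mRNA"], gene_sets, n_perm=th.n_perm,
                              seed=config.rng_seed, weight=th.gsea_weight)
            gsea.to_csv(outdir / "gsea.tsv", sep="\t", index=False,
                        float_format="%.10g")
            _stage("enrich", len(gene_sets),
                   {"ora": len(ora), "gsea": len(gsea)}, t0)

        # ---- manifest ------------------------------------------------------
        config.to_yaml(str(outdir / "config.yaml"))
        digests = {p.name: _sha256_file(p)
                   for p in sorted(outdir.rglob("*"))
                   if p.is_file() and p.name not in ("run.log",
                                                     "manifest.json",
                                                     "config.yaml")}
        # hash the parameters, not the output location
        hashed_cfg = {k: v for k, v in config.to_dict().items()
                      if k not in ("outdir", "input_dir")}
        h = hashlib.sha256()
        h.update(json.dumps(hashed_cfg, sort_keys=True).encode())
        for name in sorted(digests):
            h.update(name.encode())
            h.update(digests[name].encode())
        from . import __version__
        manifest = {"config": config.to_dict(), "seed": config.rng_seed,
                    "version": __version__,
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                    "file_sha256": digests, "bundle_hash": h.hexdigest()}
        with open(outdir / "manifest.json", "w") as fhj:
            json.dump(manifest, fhj, indent=2, sort_keys=True)

        return ResultBundle(outdir=outdir, de=de, de_counts=de_counts,
                            pairs=pairs, networks=networks,
                            summaries=summaries, hub_mrnas=hubs,
                            ora=ora, gsea=gsea, manifest=manifest)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
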