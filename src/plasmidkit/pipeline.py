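"""End-to-end pipeline over a synthetic (or provided) community.

Stages run in the published analysis order — discover -> hostlink -> circ ->
skew -> express -> protfam — and the report compares every recovered
quantity against the planted ground truth. All stochastic steps consume the
single config seed; repeated runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Any

import pandas as pd

from plasmidkit import circ, discover, express, hostlink, protfam, skew, synth
from plasmidkit.config import RunConfig
from plasmidkit.io import write_tsv

log = logging.getLogger("plasmidkit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _circular_distance(a: int, b: int, length: int) -> int:
    d = abs(a - b) % length
    return min(d, length - d)


def run_pipeline(config: RunConfig, outdir: str | None = None) -> dict[str, Any]:
    """Run every stage on a synthesized community; return the report dict."""
    report: dict[str, Any] = {"seed": config.seed}
    tables: dict[str, pd.DataFrame] = {}

    stage = "synth"
    try:
        spec = synth.CommunitySpec(seed=config.seed, **config.synth)
        community = synth.generate_community(spec)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    log.info("synth: %d contigs, %d genome read records",
             len(community.contigs), len(community.genome_alignments))

    stage = "discover"
    try:
        contigs = community.contigs
        for c in contigs:
            c.coverage = hostlink.coverage_from_alignments(
                community.genome_alignments, c.id, c.length
            )
        profiles = {c.id: discover.taxonomy_profile(c) for c in contigs}
        dcfg = config.discover
        bins = discover.bin_contigs(
            contigs,
            profiles,
            gc_window=dcfg["gc_window"],
            cov_window=dcfg["cov_window"],
            target_lineage=dcfg["target_lineage"],
            min_dominant_fraction=dcfg["min_dominant_fraction"],
        )
        candidates = discover.identify_ece_candidates(
            bins, contigs, dcfg["target_lineage"]
        )
        abundance = discover.relative_abundance(bins)
        report["n_bins"] = len(bins)
        report["n_candidates"] = len(candidates)
        report["candidates"] = [c.bin_id for c in candidates]
        tables["candidates"] = pd.DataFrame(
            [
                {
                    "bin_id": c.bin_id,
                    "contigs": ",".join(c.contig_ids),
                    "gc": round(c.mean_gc, 4),
                    "coverage": round(c.mean_coverage, 2),
                    "length": c.total_length,
                    "lineage": c.lineage,
                    "markers": ",".join(c.marker_gene_ids),
                    "abundance": round(abundance[c.bin_id], 4),
                }
                for c in candidates
            ]
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "hostlink"
    try:
        host_bins = [b for b in bins if b.role == "chromosome"]
        hosts = [(b.id, b.lineage, b.mean_coverage) for b in host_bins]
        assignments = []
        by_bin = {b.id: b for b in bins}
        for cand in candidates:
            b = by_bin[cand.bin_id]
            assignments.append(
                hostlink.assign_host(
                    b.id, b.lineage, b.mean_coverage, hosts,
                    ratio_band=tuple(config.hostlink["ratio_band"]),
                )
            )
        tables["host_assignments"] = pd.DataFrame(
            [
                {
                    "ece_id": a.ece_id,
                    "host_id": a.host_id,
                    "ratio": None if a.ratio is None else round(a.ratio, 4),
                    "class": a.abundance_class,
                    "rationale": a.rationale,
                }
                for a in assignments
            ]
        )
        if assignments and assignments[0].host_id is not None:
            report["copy_number"] = hostlink.copy_number(assignments[0])
            report["abundance_class"] = assignments[0].abundance_class
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "circ"
    try:
        ccfg = config.circ
        calls = []
        candidate_contigs = [
            cid for cand in candidates for cid in cand.contig_ids
        ]
        by_id = {c.id: c for c in contigs}
        for cid in candidate_contigs:
            calls.append(
                circ.assess_circularity(
                    cid, by_id[cid].sequence, community.genome_alignments, **ccfg
                )
            )
        tables["circularity"] = pd.DataFrame(
            [
                {
                    "contig_id": c.contig_id,
                    "overlap_len": c.overlap_len,
                    "mismatches": c.mismatches,
                    "n_spanning_pairs": c.n_spanning_pairs,
                    "is_circular": c.is_circular,
                    "circular_length": c.circular_length,
                }
                for c in calls
            ]
        )
        report["circular_calls"] = {c.contig_id: c.is_circular for c in calls}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "skew"
    try:
        scfg = config.skew
        origin_report = {}
        for call in calls:
            if not call.is_circular:
                continue
            seq = circ.trim_and_circularize(
                by_id[call.contig_id].sequence, call.overlap_len
            )
            profile = skew.windowed_skew(
                seq, window=scfg["window"], step=scfg["step"], circular=True
            )
            origin, terminus, strength = skew.predict_origin_terminus(profile)
            signal = skew.classify_bidirectional(profile, seed=config.seed)
            origin_report[call.contig_id] = {
                "origin": origin,
                "terminus": terminus,
                "signal_strength": round(strength, 3),
                "classification": signal,
            }
        report["replication"] = origin_report
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "express"
    try:
        ecfg = config.express
        filtered = express.filter_alignments(
            community.transcript_alignments,
            min_identity=ecfg["min_identity"],
            ambiguous_policy=ecfg["ambiguous_policy"],
            seed=config.seed,
        )
        genes = [g for c in contigs for g in c.genes]
        table = express.expression_table(
            filtered,
            genes,
            thresholds=tuple(ecfg["thresholds"]),
            min_frac_overlap=ecfg["min_frac_overlap"],
            seed=config.seed,
        )
        tables["expression"] = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "raw": r.raw_count,
                    "normalized": round(r.normalized, 3),
                    "tier": r.tier,
                }
                for r in table
            ]
        )
        plasmid_gene_ids = {
            g.id for g in by_id[community.plasmid_contig_id].genes
        }
        summary = express.summarize(
            r for r in table if r.gene_id in plasmid_gene_ids
        )
        report["plasmid_expression"] = dict(summary)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "protfam"
    try:
        pcfg = config.protfam
        proteins, ptruth = synth.generate_protein_universe(
            n_families=pcfg["n_families"],
            substitution_rate=pcfg["substitution_rate"],
            n_background=pcfg["n_background"],
            rng_seed=config.seed + 1,
        )
        edges = protfam.all_vs_all(
            proteins, e_max=pcfg["e_max"], cover_min=pcfg["cover_min"]
        )
        subfams = protfam.greedy_set_cover_cluster(proteins, edges)
        labels = {p.id: p.source_class for p in proteins}
        enrichment = protfam.enriched_subfamilies(
            subfams, labels, alpha=pcfg["fdr"]
        )
        tables["subfamilies"] = pd.DataFrame(
            [
                {
                    "subfamily_id": sf.id,
                    "representative": sf.representative_id,
                    "member": m,
                    "source_class": labels[m],
                }
                for sf in subfams
                for m in sf.member_ids
            ]
        )
        tables["enrichment"] = pd.DataFrame(
            [
                {
                    "subfamily": r.subfamily_id,
                    "n_plasmid": r.a,
                    "n_total": r.a + r.b,
                    "percent_enrichment": r.percent_enrichment,
                    "odds_ratio": r.odds_ratio,
                    "p": r.p,
                    "q": r.q,
                    "enriched": r.enriched,
                }
                for r in enrichment
            ]
        )
        report["n_subfamilies"] = len(subfams)
        report["n_enriched"] = sum(r.enriched for r in enrichment)
        report["family_pair_f1"] = round(
            protfam.pair_f1(ptruth.true_family_of_protein, subfams), 4
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- evaluation against planted truth
    truth = community.truth
    evaluation: dict[str, Any] = {}
    plasmid_id = community.plasmid_contig_id
    evaluation["copy_ratio_true"] = truth.true_copy_ratio
    if "copy_number" in report:
        evaluation["copy_ratio_error"] = round(
            abs(report["copy_number"] - truth.true_copy_ratio)
            / truth.true_copy_ratio,
            4,
        )
    evaluation["circularity_correct"] = all(
        report["circular_calls"].get(cid, False) == want
        for cid, want in truth.true_circular.items()
        if cid in report["circular_calls"]
    )
    if plasmid_id in report["replication"]:
        predicted = report["replication"][plasmid_id]["origin"]
        evaluation["origin_error_bp"] = _circular_distance(
            predicted, truth.true_origin, spec.plasmid_length
        )
    report["evaluation"] = evaluation

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        params = {"seed": config.seed}
        for name, df in tables.items():
            write_tsv(df, os.path.join(outdir, f"{name}.tsv"), params)
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
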