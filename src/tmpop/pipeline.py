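"""End-to-end orchestration: configuration, stage execution, and manifests.

Stages communicate only through files in the output directory, so any stage
can be re-run from its inputs.  The full default sequence is
simulate -> segments -> select -> callmut -> rates -> spectrum -> ribd ->
pav; a run writes ``manifest.json`` listing every artifact with its sha256
checksum, the per-stage ledgers, and the derived per-stage seeds.  Runs are
bit-for-bit deterministic in (config, seed).
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .calling import (
    PrefilterParams,
    SupportParams,
    apply_mutation_filters,
    mask_heterozygosity_clusters,
    prefilter_sites,
    scan_candidates,
)
from .coverage_sim import simulate_coverage
from .evidence import EvidenceParams, SiteEvidenceTable, emit_marker_genotypes, emit_site_evidence
from .genome import GeneticMap, build_genome
from .ibd_sim import PlantedWindow, simulate_ibd_tracts
from .pav import classify_te_pav, low_coverage_pav
from .pedigree import (
    PedigreeConfig,
    plant_mutations,
    plant_residual_heterozygosity,
    simulate_pedigree,
)
from .rates import estimate_rate, shared_site_generations, stratified_rates
from .ribd import call_introgression, hotspot_detection, window_nibd
from .segments import LineGenotypes, call_segments, select_lines, shared_regions
from .spectrum import clustering_test, compartment_contrast, triplet_context_table, ts_tv
from . import intervals as iv

ALL_STAGES = [
    "simulate", "segments", "select", "callmut", "rates", "spectrum", "ribd", "pav",
]

DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "outdir": "tmpop_out",
    "stages": list(ALL_STAGES),
    "genome": {
        "chrom_lengths": [2_000_000, 2_000_000],
        "genic_fraction": 0.3,
        "gc": 0.47,
        "te_fraction": 0.3,
        "centromere_fraction": 0.15,
    },
    "map": {"cm_per_chrom": 150.0},
    "pedigree": {
        "n_backcrosses": 2,
        "n_self_generations": None,
        "obligate_crossover": True,
        "n_individuals": 10,
    },
    "mutations": {"mu": 1e-6, "recurrent_fraction": 0.0},
    "residual_het": {
        "line_fraction": 0.0,
        "blocks_per_line": 1.0,
        "block_len_mean": 50_000,
    },
    "evidence": {
        "depth_mean": 20.0,
        "error_rate": 1e-3,
        "depth_model": "poisson",
        "nb_dispersion": 0.1,
        "mq_mean": 58.0,
        "mq_sd": 3.0,
        "low_mq_fraction": 0.0,
        "hq_read_prob": 1.0,
        "improper_pair_fraction": 0.0,
        "het_sites_per_kb": 1.0,
        "n_background_sites": 1000,
    },
    "markers": {"spacing": 50_000, "error_rate": 0.0, "missing_rate": 0.0},
    "ibd": {
        "n_maize": 20,
        "n_mex_panel": 8,
        "n_par_panel": 8,
        "baseline_rate": 2e-8,
        "tract_len_mean": 200_000,
        "planted_windows": [],
        "member_prob": 0.9,
    },
    "coverage": {
        "depth_mean": 30.0,
        "del_depth_mean": 0.3,
        "planted_deletions": {},
    },
    "segments": {"min_markers": 2, "switch_penalty": 1.5},
    "select": {"k": 10},
    "calling": {
        "mq_min": 30.0,
        "depth_min": 5,
        "depth_max": 40,
        "min_gap": 5,
        "minor_depth_min": 5,
        "min_mutant_hq": 5,
        "min_shared_hq": 5,
        "require_proper_pair": True,
        "mask_min_sites": 3,
        "mask_window_bp": 10_000,
        "shared_min_lines": 2,
    },
    "rates": {"g": None, "compartment_flank": 0},
    "ribd": {"window_bp": 100_000, "threshold_mode": "zscore", "z": 2.0},
    "pav": {"depth_le": 2, "merge_gap": 50, "min_len": 101, "te_threshold": 0.8},
}


def _check_keys(cfg: Dict[str, Any], ref: Dict[str, Any], path: str = "") -> None:
    for k, v in cfg.items():
        if k not in ref:
            raise ValueError(f"unknown config key: {path}{k}")
        if isinstance(v, dict) and isinstance(ref[k], dict) and ref[k]:
            _check_keys(v, ref[k], f"{path}{k}.")


@dataclass
class RunConfig:
    data: Dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, overrides: Dict[str, Any]) -> "RunConfig":
        _check_keys(overrides, DEFAULT_CONFIG)
        data = copy.deepcopy(DEFAULT_CONFIG)

        def merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    merge(dst[k], v)
                else:
                    dst[k] = v

        merge(data, overrides)
        return cls(data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(root_seed: int) -> Dict[str, int]:
    names = ["genome", "pedigree", "mutations", "het", "evidence", "markers", "ibd", "coverage"]
    state = np.random.SeedSequence(root_seed).generate_state(len(names))
    return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def run_pipeline(config: RunConfig, seed: Optional[int] = None,
                 outdir: Optional[str | Path] = None) -> Dict[str, Any]:
    """Execute the configured stages; returns (and writes) the manifest."""
    cfg = config.data
    seed = cfg["seed"] if seed is None else seed
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    manifest: Dict[str, Any] = {"seed": seed, "stage_seeds": seeds, "stages": []}

    genome = None
    truth = None

    def record(name: str, t0: float, outputs: List[Path], **counters) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "duration_s": round(time.time() - t0, 3),
                "outputs": [
                    {"path": p.name, "sha256": _sha256(p)} for p in outputs
                ],
                "counters": counters,
            }
        )

    def load_genome():
        return tio.read_genome_json(out / "genome.json", out / "genome.fasta")

    for stage in cfg["stages"]:
        t0 = time.time()
        if stage == "simulate":
            gcfg = cfg["genome"]
            genome = build_genome(
                gcfg["chrom_lengths"],
                genic_fraction=gcfg["genic_fraction"],
                gc=gcfg["gc"],
                te_fraction=gcfg["te_fraction"],
                centromere_fraction=gcfg["centromere_fraction"],
                seed=seeds["genome"],
            )
            genome.write_fasta(out / "genome.fasta")
            tio.write_genome_json(genome, out / "genome.json")
            gmap = GeneticMap.uniform(genome.chrom_lengths, cfg["map"]["cm_per_chrom"])
            pcfg = PedigreeConfig(
                n_backcrosses=cfg["pedigree"]["n_backcrosses"],
                n_self_generations=cfg["pedigree"]["n_self_generations"],
                obligate_crossover=cfg["pedigree"]["obligate_crossover"],
                seed=seeds["pedigree"],
            )
            truth = simulate_pedigree(
                genome, gmap, pcfg, cfg["pedigree"]["n_individuals"]
            )
            plant_mutations(
                truth, genome, cfg["mutations"]["mu"], seed=seeds["mutations"],
                recurrent_fraction=cfg["mutations"]["recurrent_fraction"],
            )
            plant_residual_heterozygosity(
                truth, seed=seeds["het"], **cfg["residual_het"]
            )
            tio.write_segments(
                [truth.lines[l].segments for l in truth.line_ids],
                out / "truth_segments.bed",
            )
            muts = truth.all_mutations()
            pd.DataFrame(
                [
                    {
                        "chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt,
                        "carriers": ",".join(m.carriers),
                        "generation": m.generation, "origin": m.origin,
                    }
                    for m in muts
                ]
            ).to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
            ev = emit_site_evidence(
                truth, genome, EvidenceParams(**cfg["evidence"]), seed=seeds["evidence"]
            )
            ev.to_vcf(out / "evidence.vcf", genome.chrom_lengths)
            markers = emit_marker_genotypes(
                truth,
                spacing=cfg["markers"]["spacing"],
                error_rate=cfg["markers"]["error_rate"],
                missing_rate=cfg["markers"]["missing_rate"],
                seed=seeds["markers"],
            )
            tio.write_genotypes(markers, out / "markers.tsv")
            icfg = cfg["ibd"]
            tracts = simulate_ibd_tracts(
                genome.chrom_lengths,
                icfg["n_maize"], icfg["n_mex_panel"], icfg["n_par_panel"],
                baseline_rate=icfg["baseline_rate"],
                tract_len_mean=icfg["tract_len_mean"],
                planted_windows=[PlantedWindow(**w) for w in icfg["planted_windows"]],
                member_prob=icfg["member_prob"],
                seed=seeds["ibd"],
            )
            tio.write_tracts(tracts, out / "tracts.tsv")
            ccfg = cfg["coverage"]
            depth, pav_truth = simulate_coverage(
                genome.chrom_lengths,
                planted_deletions={
                    c: [tuple(t) for t in v]
                    for c, v in ccfg["planted_deletions"].items()
                },
                depth_mean=ccfg["depth_mean"],
                del_depth_mean=ccfg["del_depth_mean"],
                seed=seeds["coverage"],
            )
            tio.write_bedgraph(depth, out / "coverage.bedgraph")
            tio.write_bed(
                pd.DataFrame(
                    [
                        (c, s, e, "deletion", 0, ".")
                        for c, ivs in pav_truth.items()
                        for s, e in ivs
                    ],
                    columns=tio.BED6_COLUMNS,
                ),
                out / "pav_truth.bed",
            )
            record(
                stage, t0,
                [out / f for f in (
                    "genome.fasta", "genome.json", "truth_segments.bed",
                    "truth_mutations.tsv", "evidence.vcf", "markers.tsv",
                    "tracts.tsv", "coverage.bedgraph", "pav_truth.bed",
                )],
                n_lines=len(truth.line_ids), n_true_mutations=len(muts),
            )

        elif stage == "segments":
            genome = genome or load_genome()
            markers = tio.read_genotypes(out / "markers.tsv")
            segsets = []
            for lid, sub in markers.groupby("line_id"):
                g = LineGenotypes(str(lid), sub[["chrom", "pos", "code"]].reset_index(drop=True))
                segsets.append(
                    call_segments(
                        g, genome.chrom_lengths,
                        min_markers=cfg["segments"]["min_markers"],
                        switch_penalty=cfg["segments"]["switch_penalty"],
                    )
                )
            tio.write_segments(segsets, out / "segments.bed")
            record(stage, t0, [out / "segments.bed"], n_lines=len(segsets))

        elif stage == "select":
            segsets = tio.read_segments(out / "segments.bed")
            res = select_lines(segsets, cfg["select"]["k"])
            (out / "selection.json").write_text(
                json.dumps(
                    {
                        "line_ids": res.line_ids,
                        "coverage_fractions": res.coverage_fractions,
                        "per_line_donor_fraction": res.per_line_donor_fraction,
                    },
                    indent=1,
                )
            )
            record(stage, t0, [out / "selection.json"],
                   coverage=res.coverage_fractions[-1])

        elif stage == "callmut":
            genome = genome or load_genome()
            ev = SiteEvidenceTable.from_vcf(out / "evidence.vcf")
            segsets = tio.read_segments(out / "segments.bed")
            ccfg = cfg["calling"]
            shared = shared_regions(segsets, "MO17", ccfg["shared_min_lines"])
            filt, pre_ledger = prefilter_sites(
                ev,
                PrefilterParams(
                    mq_min=ccfg["mq_min"], depth_min=ccfg["depth_min"],
                    depth_max=ccfg["depth_max"], min_gap=ccfg["min_gap"],
                    minor_depth_min=ccfg["minor_depth_min"],
                ),
            )
            cands, hets = scan_candidates(filt, shared)
            mask_sites = pd.concat(
                [cands[["chrom", "pos"]], hets], ignore_index=True
            )
            boundaries = {
                c: sorted({s for ss in segsets for s, e, *_ in ss.intervals.get(c, [])}
                          | {e for ss in segsets for s, e, *_ in ss.intervals.get(c, [])})
                for c in genome.chrom_lengths
            }
            masks = mask_heterozygosity_clusters(
                mask_sites, ccfg["mask_min_sites"], ccfg["mask_window_bp"], boundaries
            )
            records, ledger = apply_mutation_filters(
                cands, filt, masks,
                SupportParams(
                    min_mutant_hq=ccfg["min_mutant_hq"],
                    min_shared_hq=ccfg["min_shared_hq"],
                    require_proper_pair=ccfg["require_proper_pair"],
                ),
                genome=genome,
            )
            tio.write_mutations(records, out / "mutations.tsv")
            tio.write_bed(
                pd.DataFrame(
                    [(c, s, e, "hetmask", 0, ".") for c, ivs in masks.items()
                     for s, e in ivs],
                    columns=tio.BED6_COLUMNS,
                ),
                out / "masks.bed",
            )
            record(stage, t0, [out / "mutations.tsv", out / "masks.bed"],
                   prefilter=pre_ledger, filters=ledger)

        elif stage == "rates":
            genome = genome or load_genome()
            segsets = tio.read_segments(out / "segments.bed")
            records = tio.read_mutations(out / "mutations.tsv")
            masks_bed = tio.read_bed(out / "masks.bed")
            masks: Dict[str, list] = {}
            for row in masks_bed.itertuples(index=False):
                masks.setdefault(row.chrom, []).append((row.start, row.end))
            g = cfg["rates"]["g"] or PedigreeConfig(
                n_backcrosses=cfg["pedigree"]["n_backcrosses"],
                n_self_generations=cfg["pedigree"]["n_self_generations"],
            ).total_generations
            shared = shared_regions(
                tio.read_segments(out / "segments.bed"), "MO17",
                cfg["calling"]["shared_min_lines"],
            )
            callable_mask = {
                c: iv.complement(masks.get(c, []), L)
                for c, L in genome.chrom_lengths.items()
            }
            denom = shared_site_generations(shared, g, callable_mask)
            overall = estimate_rate(len(records), denom)
            per_line_callable = {
                ss.line_id: {
                    c: iv.intersect(ivs, callable_mask[c])
                    for c, ivs in ss.intervals_of("MO17").items()
                }
                for ss in segsets
            }
            tables = []
            for scheme in ("feature", "compartment", "chromosome"):
                t = stratified_rates(
                    records, genome, per_line_callable, g, scheme,
                    cfg["rates"]["compartment_flank"],
                ).reset_index()
                t.insert(0, "scheme", scheme)
                tables.append(t)
            df = pd.concat(
                [
                    pd.DataFrame(
                        [{
                            "scheme": "all", "stratum": "all", "n": overall.n_mutations,
                            "site_generations": overall.site_generations,
                            "rate": overall.rate,
                            "ci_low": overall.poisson_ci95[0],
                            "ci_high": overall.poisson_ci95[1],
                        }]
                    ),
                    *tables,
                ],
                ignore_index=True,
            )
            df.to_csv(out / "rates.tsv", sep="\t", index=False)
            record(stage, t0, [out / "rates.tsv"], rate=overall.rate, n=overall.n_mutations)

        elif stage == "spectrum":
            genome = genome or load_genome()
            records = tio.read_mutations(out / "mutations.tsv")
            doc: Dict[str, Any] = {"n": len(records)}
            if records:
                ts, tv, ratio = ts_tv([(r.ref, r.alt) for r in records])
                doc["ts"], doc["tv"], doc["ts_tv"] = ts, tv, ratio
                table, ledger = triplet_context_table(records, genome)
                table.to_csv(out / "triplets.tsv", sep="\t")
                doc["triplet_ledger"] = ledger
                doc["compartment_contrast"] = (
                    compartment_contrast(records).reset_index().to_dict("records")
                )
                if len(records) >= 10:
                    res = clustering_test(
                        [(r.chrom, r.pos - 1) for r in records],
                        genome.callable_intervals,
                        n_null=100,
                        seed=seed,
                    )
                    doc["cluster_D"] = res.statistic
                    doc["cluster_p"] = res.pvalue
            else:
                pd.DataFrame().to_csv(out / "triplets.tsv", sep="\t")
            (out / "spectrum.json").write_text(json.dumps(doc, indent=1))
            record(stage, t0, [out / "spectrum.json", out / "triplets.tsv"])

        elif stage == "ribd":
            genome = genome or load_genome()
            tracts = tio.read_tracts(out / "tracts.tsv")
            ws = window_nibd(
                tracts, genome.chrom_lengths, cfg["ribd"]["window_bp"],
                panel_sizes={
                    "mex": cfg["ibd"]["n_mex_panel"],
                    "par": cfg["ibd"]["n_par_panel"],
                },
                maize_lines=[
                    f"L{i + 1:04d}" for i in range(cfg["ibd"]["n_maize"])
                ],
            )
            snp_density = np.ones(len(ws.df))
            try:
                summary = call_introgression(
                    ws, snp_density, cfg["ribd"]["threshold_mode"], cfg["ribd"]["z"]
                )
                flagged = summary.flagged
                hot = hotspot_detection(summary, min_lines=2)
                counters = {
                    "mu": summary.mu, "sigma": summary.sigma,
                    "n_flagged": int(len(flagged)),
                    "union_proportion": summary.union_proportion(genome.total_length),
                    "hotspots": len(hot),
                }
                summary.windows.to_csv(out / "windows.tsv", sep="\t", index=False)
                tio.write_bed(
                    flagged.assign(name="introgression", score=0, strand=".")[
                        tio.BED6_COLUMNS
                    ],
                    out / "introgression.bed",
                )
            except ValueError as e:  # degenerate null scan (sigma == 0)
                ws.df.to_csv(out / "windows.tsv", sep="\t", index=False)
                tio.write_bed(pd.DataFrame(columns=tio.BED6_COLUMNS), out / "introgression.bed")
                counters = {"error": str(e)}
            record(stage, t0, [out / "windows.tsv", out / "introgression.bed"], **counters)

        elif stage == "pav":
            genome = genome or load_genome()
            depth = tio.read_bedgraph(out / "coverage.bedgraph", genome.chrom_lengths)
            pcfg = cfg["pav"]
            pavs = low_coverage_pav(
                depth, pcfg["depth_le"], pcfg["merge_gap"], pcfg["min_len"]
            )
            pavs = classify_te_pav(pavs, genome.te_intervals, pcfg["te_threshold"])
            tio.write_bed(
                pd.DataFrame(
                    [
                        (p.chrom, p.start, p.end,
                         f"pav:te={p.te_fraction:.2f}", int(p.te_related), ".")
                        for p in pavs
                    ],
                    columns=tio.BED6_COLUMNS,
                ),
                out / "pav.bed",
            )
            record(stage, t0, [out / "pav.bed"], n_pav=len(pavs))

        else:
            raise ValueError(f"unknown stage {stage!r}")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
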