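"""End-to-end orchestration: simulate (or load) clusters, then run the
conservation, repeat and relative-rate stages and write tables.

Every run is reproducible: all randomness flows from the single config
seed through per-stage derived seeds, and each output table starts with a
header line recording the config hash and seed, so re-running with an
identical config gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation, repeats, rrt, synthetic_data
from .conservation import GROUPS, ConservationThresholds
from .repeats import RepeatSearchParams
from .seq_io import GenomicInterval, UsageError, write_bed, write_fasta
from .synthetic_data import (
    CNESpec,
    ConfigError,
    ExonSpec,
    RepeatSpec,
    SimulationConfig,
)

logger = logging.getLogger("hoxcomp")


@dataclass
class SpeciesRoles:
    reference: str
    outgroup: str
    ingroups: list[str] = field(default_factory=list)
    # group label -> diagnostic species (e.g. gnathostome -> elephant_shark)
    diagnostic: dict[str, str] = field(default_factory=dict)


@dataclass
class AnalysisConfig:
    """All fixed constants of an analysis run.

    Defaults follow the standard desk values: CNEs at >=65 % identity over
    >=50 bp, repeat arms at >=70 % identity, long arms >100 bp, and
    significance tiers at p <= 0.01 / 0.05.
    """

    roles: SpeciesRoles
    min_identity: float = 65.0
    min_length: int = 50
    min_arm_identity: float = 70.0
    min_arm_length: int = 50
    long_arm_threshold: int = 100
    p_high: float = 0.01
    p_significant: float = 0.05
    clade_priority: tuple[str, ...] = GROUPS
    seed: int = 0
    simulation: SimulationConfig | None = None

    def validate(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ConfigError("min_identity must be in (0, 100]")
        if not 0 < self.min_arm_identity <= 100:
            raise ConfigError("min_arm_identity must be in (0, 100]")
        if self.min_length < 1 or self.min_arm_length < 1:
            raise ConfigError("length thresholds must be >= 1")
        if not 0 < self.p_high < self.p_significant < 1:
            raise ConfigError("significance tiers must satisfy 0 < high < significant < 1")
        if tuple(sorted(self.clade_priority)) != tuple(sorted(GROUPS)):
            raise ConfigError("clade_priority must permute the four groups")
        for label in self.roles.diagnostic:
            if label not in GROUPS:
                raise ConfigError(f"unknown clade label {label!r}")
        if not self.roles.reference or not self.roles.outgroup:
            raise ConfigError("reference and outgroup roles are required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clade_priority"] = list(self.clade_priority)
        if self.simulation is not None:
            sim = d["simulation"]
            sim["cne_spec"] = [
                {**c, "retained_in": sorted(c["retained_in"]) if c["retained_in"] else None}
                for c in sim["cne_spec"]
            ]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        roles = SpeciesRoles(**raw.pop("roles"))
        sim_raw = raw.pop("simulation", None)
        sim = None
        if sim_raw is not None:
            sim = SimulationConfig(
                tree=sim_raw["tree"],
                rate_multipliers=sim_raw.get("rate_multipliers", {}),
                seq_length=sim_raw.get("seq_length", 20_000),
                cne_spec=[
                    CNESpec(
                        position=c["position"],
                        length=c["length"],
                        conservation_scaling=c.get("conservation_scaling", 0.05),
                        retained_in=(
                            frozenset(c["retained_in"])
                            if c.get("retained_in")
                            else None
                        ),
                    )
                    for c in sim_raw.get("cne_spec", [])
                ],
                repeat_spec=[
                    RepeatSpec(**r) for r in sim_raw.get("repeat_spec", [])
                ],
                exon_spec=[ExonSpec(**e) for e in sim_raw.get("exon_spec", [])],
                cluster_name=sim_raw.get("cluster_name", "HoxA"),
                seed=sim_raw.get("seed", 0),
            )
        raw.pop("clade_priority", None)
        return cls(roles=roles, simulation=sim, **raw)


def _stage_seed(base_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write_table(df, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> Path:
    """Run every stage in dependency order and write tables into
    ``out_dir``: simulated FASTA + ground-truth BEDs, CNE calls and group
    summary, repeat pairs and densities, RRT results, Hasse diagrams and
    the pairwise summary. Returns the run directory."""
    config.validate()
    if config.simulation is None:
        raise UsageError(
            "run_pipeline currently requires a simulation block; for "
            "pre-existing FASTA inputs call the stage functions directly"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# hoxcomp config_hash={config.config_hash()} seed={config.seed}\n"

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_stages(config, out, header)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: AnalysisConfig, out: Path, header: str) -> Path:
    roles = config.roles
    sim_conf = config.simulation
    assert sim_conf is not None
    sim_conf = SimulationConfig(
        tree=sim_conf.tree,
        rate_multipliers=sim_conf.rate_multipliers,
        seq_length=sim_conf.seq_length,
        cne_spec=sim_conf.cne_spec,
        repeat_spec=sim_conf.repeat_spec,
        exon_spec=sim_conf.exon_spec,
        cluster_name=sim_conf.cluster_name,
        seed=_stage_seed(config.seed, "simulate"),
    )

    logger.info("stage simulate: %d bp, tree %s", sim_conf.seq_length, sim_conf.tree)
    truth = synthetic_data.simulate_clusters(sim_conf)
    species = sorted(truth.clusters)
    for role_sp in [roles.reference, roles.outgroup, *roles.ingroups]:
        if role_sp not in species:
            raise ConfigError(f"species role {role_sp!r} missing from tree")

    write_fasta(
        out / "clusters.fa",
        [(sp, truth.clusters[sp].sequence) for sp in species],
    )
    for sp in species:
        write_bed(
            out / f"truth_cnes.{sp}.bed", truth.cne_intervals[sp]
        )
    logger.info("stage simulate: %d species written", len(species))

    ref = roles.reference
    ref_cluster = truth.clusters[ref]
    thresholds = ConservationThresholds(config.min_identity, config.min_length)
    coding_mask = truth.exon_intervals[ref]

    per_species_hits: dict[str, list[GenomicInterval]] = {}
    ref_cnes: list[conservation.CNERecord] = []
    for sp in species:
        if sp == ref:
            continue
        aln = conservation.global_align(
            ref_cluster.sequence,
            truth.clusters[sp].sequence,
            ref_species=ref,
            other_species=sp,
        )
        cnes = conservation.call_cnes(aln, thresholds, coding_mask)
        per_species_hits[sp] = [rec.interval for rec in cnes]
        logger.info("stage cne: %s vs %s -> %d CNEs", ref, sp, len(cnes))
        if not ref_cnes:
            ref_cnes = cnes  # reference CNE set: first comparison species
    presence = {label: {sp} for label, sp in roles.diagnostic.items()}
    classified = conservation.classify_cne_groups(
        ref_cnes, presence, per_species_hits
    )
    write_bed(
        out / "cnes.bed",
        [(rec.interval, rec.group) for rec in classified],
        scores=[round(rec.identity, 1) for rec in classified],
    )
    summary = conservation.cne_summary_table(
        {sim_conf.cluster_name: classified}
    )
    _write_table(summary, out / "cne_summary.tsv", header)

    params = RepeatSearchParams(
        min_arm_identity=config.min_arm_identity,
        min_arm_length=config.min_arm_length,
        long_arm_threshold=config.long_arm_threshold,
    )
    pairs = repeats.find_repeat_pairs(ref_cluster.sequence, params, seq_id=ref)
    long_inv = repeats.long_inverted_repeats(pairs, params)
    logger.info(
        "stage repeats: %d pairs, %d long inverted", len(pairs), len(long_inv)
    )
    _write_table(repeats.repeat_pairs_table(pairs), out / "repeat_pairs.tsv", header)
    hits = [iv for p in pairs for iv in (p.arm1, p.arm2)]
    density = repeats.repeat_density(hits, len(ref_cluster.sequence))
    _write_table(
        pd.DataFrame(
            [{"species": ref, "density_pct": round(density, 3)}]
        ),
        out / "repeat_density.tsv",
        header,
    )

    gene_alignments: dict[str, dict[str, str]] = {}
    for i, iv in enumerate(truth.exon_intervals[ref]):
        gene_alignments[f"gene{i:02d}"] = {
            sp: truth.clusters[sp].sequence[iv.start : iv.end] for sp in species
        }
    results = rrt.rrt_battery(
        gene_alignments, roles.ingroups, roles.outgroup, "nucleotide"
    )
    logger.info("stage rrt: %d results over %d genes", len(results), len(gene_alignments))
    results_df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "species_a": r.species_a,
                "species_b": r.species_b,
                "outgroup": r.outgroup,
                "n_sites": r.n_sites_used,
                "m_a": r.m_a,
                "m_b": r.m_b,
                "chi2": round(r.chi2, 4),
                "p": f"{r.p:.6g}",
                "significance": r.significance,
            }
            for r in results
        ]
    )
    _write_table(results_df, out / "rrt_results.tsv", header)
    _write_table(rrt.summarize_pairwise(results), out / "rrt_pairwise.tsv", header)
    by_gene: dict[str, list[rrt.RRTResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    with open(out / "hasse.dot", "w") as fh:
        for gene in sorted(by_gene):
            order = rrt.build_hasse(by_gene[gene])
            fh.write(rrt.hasse_to_dot(order, gene) + "\n")
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, sort_keys=True, indent=1)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out
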