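"""End-to-end orchestration: simulate -> screen -> validate -> map -> trees -> turnover.

A single declarative YAML config drives the whole demo workflow on synthetic
catalogs.  Every stage writes its tabular outputs into a per-stage
subdirectory of the run directory, each TSV carrying the config hash and seed
in a leading comment line; ``MANIFEST.json`` lists the hash, the seed and all
files.  Runs are idempotent given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import genetree, io_formats, mapping, screen, synthdata, turnover, validate
from .io_formats import Sex
from .search import exact_search

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "DEMO_CONFIG"]

# Nine synthetic species, one (sp1) with a non-homologous sex chromosome:
# exactly one planted turnover, two identities, no heterogamety shift.
# sp3/sp4 share an ancestral-SDR tag (an "alternate species pair").
DEMO_CONFIG: dict[str, Any] = {
    "seed": 1,
    "alpha": 0.05,
    "coverage": 1,
    "simulation": {
        "n_species": 9,
        "n_males": 10,
        "n_females": 10,
        "n_autosomal_loci": 60,
        "n_xy_snp_loci": 25,
        "n_y_limited_loci": 8,
        "system": "XY",
        "sdr_shared_species": ["sp3", "sp4"],
        "sex_chromosome": {"sp1": "chr8"},
    },
    "screen": {},
    "assignment": {},
    "trees": {
        "n_bootstrap": 100,
        "support_threshold": 50.0,
        "scenario_species": {
            "ancestral_suppression": ["sp3", "sp4"],
            "ongoing_recombination": ["sp2", "sp3", "sp4", "sp5",
                                      "sp6", "sp7", "sp8", "sp9"],
        },
    },
}

_TOP_KEYS = {"seed", "alpha", "coverage", "simulation", "screen", "assignment", "trees"}
_TREE_KEYS = {"n_bootstrap", "support_threshold", "scenario_species"}


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: float = 0.05
    coverage: int = 1
    simulation: synthdata.SimulationConfig = field(
        default_factory=synthdata.SimulationConfig
    )
    thresholds: screen.ScreenThresholds = field(
        default_factory=screen.ScreenThresholds
    )
    rules: mapping.AssignmentRules = field(default_factory=mapping.AssignmentRules)
    n_bootstrap: int = 100
    support_threshold: float = 50.0
    scenario_species: dict[str, list[str]] = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(section: str, factory, **extra):
            payload = dict(data.get(section, {}))
            names = {f.name for f in dataclasses.fields(factory)}
            bad = set(payload) - names
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            payload.update(extra)
            return factory(**payload)

        seed = int(data.get("seed", 0))
        sim_payload = dict(data.get("simulation", {}))
        if "sdr_shared_species" in sim_payload:
            sim_payload["sdr_shared_species"] = tuple(
                sim_payload["sdr_shared_species"]
            )
        sim_payload.setdefault("seed", seed)
        sim_names = {f.name for f in dataclasses.fields(synthdata.SimulationConfig)}
        bad = set(sim_payload) - sim_names
        if bad:
            raise ValueError(f"unknown keys in [simulation]: {sorted(bad)}")
        trees = dict(data.get("trees", {}))
        bad = set(trees) - _TREE_KEYS
        if bad:
            raise ValueError(f"unknown keys in [trees]: {sorted(bad)}")
        return cls(
            seed=seed,
            alpha=float(data.get("alpha", 0.05)),
            coverage=int(data.get("coverage", 1)),
            simulation=synthdata.SimulationConfig(**sim_payload),
            thresholds=build("screen", screen.ScreenThresholds),
            rules=build("assignment", mapping.AssignmentRules),
            n_bootstrap=int(trees.get("n_bootstrap", 100)),
            support_threshold=float(trees.get("support_threshold", 50.0)),
            scenario_species=dict(trees.get("scenario_species", {})),
            raw=dict(data),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        missing = [k for k in ("simulation",) if k not in data]
        if missing:
            raise ValueError(f"config missing required section(s): {missing}")
        return cls.from_mapping(data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw or {}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> str:
    return f"# config_hash={cfg.config_hash} seed={cfg.seed}\n"


def _write_tsv(path: Path, header: list[str], rows: list[list], cfg: PipelineConfig):
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: PipelineConfig | Mapping[str, Any], out_dir: str | Path) -> dict:
    """Run every stage on synthetic data and return the machine-readable summary.

    The summary (also written to ``summary.json``) reports per-species
    candidate and confirmed-marker counts, heterogamety calls, chromosome
    assignments and concentration tests, trans-species shared loci, the two
    gene-history scenario classifications, and the turnover counts.
    """
    cfg = config if isinstance(config, PipelineConfig) \
        else PipelineConfig.from_mapping(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", json.dumps(cfg.raw, sort_keys=True, default=str))
    manifest_files: list[str] = []

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    summary: dict[str, Any] = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "species": {},
    }

    # --- simulate -----------------------------------------------------------
    sim_dir = stage_dir("simulate")
    study = synthdata.simulate_catalog(cfg.simulation)
    io_formats.write_registry(study.registry, sim_dir / "registry.tsv")
    io_formats.write_fasta(study.reference.sequences, sim_dir / "reference.fasta")
    manifest_files += ["simulate/registry.tsv", "simulate/reference.fasta"]
    for sp, catalog in study.catalogs.items():
        io_formats.write_catalog(
            catalog,
            sim_dir / f"{sp}.genotypes.tsv",
            sim_dir / f"{sp}.presence.tsv",
            sim_dir / f"{sp}.consensus.fasta",
        )
        manifest_files += [
            f"simulate/{sp}.genotypes.tsv", f"simulate/{sp}.presence.tsv",
            f"simulate/{sp}.consensus.fasta",
        ]
    _write_tsv(
        sim_dir / "truth.tsv",
        ["species_id", "locus_id", "class", "sex_linked", "chromosome",
         "position", "unified_id"],
        [[r.species_id, r.locus_id, r.locus_class, int(r.sex_linked),
          r.chromosome, r.position, r.unified_id or "-"]
         for r in study.truth.records],
        cfg,
    )
    manifest_files.append("simulate/truth.tsv")

    # --- screen + validate --------------------------------------------------
    screen_dir = stage_dir("screen")
    val_dir = stage_dir("validate")
    confirmed_by_species: dict[str, list[screen.CandidateMarker]] = {}
    for sp, catalog in study.catalogs.items():
        candidates = screen.screen_all(
            catalog, study.registry, cfg.thresholds, species_id=sp
        )
        _write_tsv(
            screen_dir / f"{sp}.candidates.tsv",
            ["locus_id", "site", "strategies", "system", "sex_specific_allele"],
            [[m.locus_id, m.site if m.site is not None else "-",
              ",".join(sorted(m.strategies)), m.system_consistency,
              m.sex_specific_allele or "-"] for m in candidates],
            cfg,
        )
        manifest_files.append(f"screen/{sp}.candidates.tsv")

        pools = synthdata.simulate_reads(
            catalog, study.registry, cfg.coverage, cfg.seed
        )
        results = validate.validate_markers(
            candidates, pools[Sex.MALE], pools[Sex.FEMALE],
            evalue_cutoff=cfg.rules.evalue_cutoff,
        )
        confirmed = [r.marker for r in results if r.status == "confirmed"]
        confirmed_by_species[sp] = confirmed
        call = validate.call_system(confirmed, alpha=cfg.alpha, species_id=sp)
        _write_tsv(
            val_dir / f"{sp}.validated.tsv",
            ["locus_id", "site", "system", "status", "n_het_pool", "n_hom_pool"],
            [[r.marker.locus_id,
              r.marker.site if r.marker.site is not None else "-",
              r.marker.system_consistency, r.status,
              r.n_heterogametic_occurrences, r.n_homogametic_occurrences]
             for r in results],
            cfg,
        )
        manifest_files.append(f"validate/{sp}.validated.tsv")
        summary["species"][sp] = {
            "n_candidates": len(candidates),
            "n_confirmed": len(confirmed),
            "system_call": call.call,
            "system_p_value": call.p_value,
            "n_confirmed_xy": call.n_confirmed_xy,
            "n_confirmed_zw": call.n_confirmed_zw,
        }

    # trans-species sharing via the unified-catalog translation
    unified = study.truth.unified_map()
    translation: dict[str, dict[str, str]] = {sp: {} for sp in study.catalogs}
    for uid, by_sp in unified.items():
        for sp, lid in by_sp.items():
            translation[sp][lid] = uid
    sharing = validate.find_trans_species_markers(confirmed_by_species, translation)
    summary["trans_species"] = {
        "n_shared_loci": len(sharing["shared"]),
        "shared": {
            s.unified_id: sorted(s.species) for s in sharing["shared"]
        },
        "maximal_sharing_set": sorted(sharing["maximal_sharing_set"]),
    }

    # --- map ----------------------------------------------------------------
    map_dir = stage_dir("map")
    identity: dict[str, str] = {}
    heterogamety: dict[str, str] = {}
    for sp in study.catalogs:
        markers = confirmed_by_species[sp]
        system_call = summary["species"][sp]["system_call"]
        kept = [
            m for m in markers
            if system_call == "undetermined"
            or m.system_consistency == f"{system_call}_type"
        ]
        queries = {f"{m.locus_id}|{m.site}": m.consensus for m in kept}
        hits = exact_search(queries, study.reference.sequences)
        assignments = mapping.assign_direct(hits, cfg.rules)
        report = mapping.concentration_test(
            assignments, study.reference, alpha=cfg.alpha
        )
        _write_tsv(
            map_dir / f"{sp}.assignments.tsv",
            ["marker_id", "chromosome", "reason", "position", "method"],
            [[a.marker_id, a.chromosome or "-", a.reason or "-",
              a.position if a.position is not None else "-", a.method]
             for a in assignments],
            cfg,
        )
        manifest_files.append(f"map/{sp}.assignments.tsv")
        assigned = [a for a in assignments if a.assigned]
        chrom_counts = Counter(a.chromosome for a in assigned)
        summary["species"][sp].update(
            {
                "n_assigned": len(assigned),
                "fraction_unmapped": report.fraction_unmapped,
                "assignments_by_chromosome": dict(sorted(chrom_counts.items())),
                "concentrated_chromosomes": report.concentrated_chromosomes,
            }
        )
        if chrom_counts:
            identity[sp] = chrom_counts.most_common(1)[0][0]
        else:
            identity[sp] = turnover.UNKNOWN
        heterogamety[sp] = (
            system_call if system_call in {"XY", "ZW"} else turnover.UNKNOWN
        )

    # --- trees --------------------------------------------------------------
    tree_dir = stage_dir("trees")
    summary["gene_trees"] = {}
    for scenario, species_list in sorted(cfg.scenario_species.items()):
        alleles = synthdata.simulate_gene_history(
            scenario, species_list, cfg.simulation.species_tree,
            mutation_rate=cfg.simulation.mutation_rate, seed=cfg.seed,
            locus_length=cfg.simulation.locus_length,
            ts_tv_ratio=cfg.simulation.ts_tv_ratio,
        )
        alignment = {a.label: a.sequence for a in alleles}
        labels = {a.label: (a.species_id, a.allele_class) for a in alleles}
        tree, supports = genetree.bootstrap_supports(
            alignment, cfg.n_bootstrap, cfg.seed
        )
        cls = genetree.classify_topology(
            tree, labels, cfg.support_threshold, supports
        )
        newick_path = tree_dir / f"{scenario}.nwk"
        io_formats.write_newick(tree, newick_path)
        manifest_files.append(f"trees/{scenario}.nwk")
        summary["gene_trees"][scenario] = {
            "classification": cls,
            "n_tips": len(alignment),
            "species": sorted(set(species_list)),
        }

    # --- turnover -----------------------------------------------------------
    turn_dir = stage_dir("turnover")
    phylo = turnover.IdentityPhylogeny(
        tree=cfg.simulation.species_tree,
        identity=identity,
        heterogamety=heterogamety,
    )
    report = phylo.report()
    (turn_dir / "tree_annotation.txt").write_text(
        _stamp(cfg) + phylo.render() + "\n"
    )
    _write_tsv(
        turn_dir / "turnover.tsv",
        ["quantity", "value"],
        [
            ["min_turnovers", report.min_turnovers],
            ["n_identities", report.n_identities],
            ["min_heterogamety_shifts",
             report.min_heterogamety_shifts
             if report.min_heterogamety_shifts is not None else "-"],
            ["turnover_branches",
             ";".join(",".join(sorted(b)) for b in sorted(
                 report.turnover_branches, key=sorted))],
        ],
        cfg,
    )
    manifest_files += ["turnover/tree_annotation.txt", "turnover/turnover.tsv"]
    summary["turnover"] = {
        "min_turnovers": report.min_turnovers,
        "n_identities": report.n_identities,
        "min_heterogamety_shifts": report.min_heterogamety_shifts,
        "identity_by_species": dict(sorted(identity.items())),
        "turnover_branches": [sorted(b) for b in sorted(
            report.turnover_branches, key=sorted)],
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest_files.append("summary.json")
    (out / "MANIFEST.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash,
                "seed": cfg.seed,
                "config": cfg.raw,
                "files": sorted(manifest_files),
            },
            indent=2, sort_keys=True, default=str,
        )
    )
    return summary
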