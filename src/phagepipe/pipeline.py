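"""End-to-end orchestration of the annotation stages.

Stage order: layout -> consensus -> annotation -> curation -> summaries ->
lifestyle -> clustering -> acr.  A single config dict (YAML on disk) names
every threshold with its standard default; a demo configuration generates
all inputs synthetically so the whole pipeline runs self-contained.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import acr_screen, classification, curation, genome_layout, synthetic_data
from .annotation_transfer import (
    ReannotationTable,
    apply_reannotation,
    assign_phrog,
    select_best_hit,
    summarize_annotation,
)
from .consensus import (
    agreement_stats,
    consensus_keep_policy,
    flag_outlier_callers,
    merge_predictions,
)
from .curation import curate_genome, orf_feature_id
from .errors import ConfigurationError, PhagePipeError
from .io_formats import (
    read_caller_predictions,
    read_genomes_fasta,
    read_hit_table,
    read_similarity_matrix,
    write_annotation,
    write_similarity_matrix,
)
from .synthetic_data import DEFAULT_CALLERS

DEFAULT_THRESHOLDS: dict[str, float] = {
    "phrog_prob": 80.0,
    "phrog_evalue": 1e-4,
    "pdb_prob": 80.0,
    "pdb_evalue": 1e-3,
    "pdb_coverage": 0.5,
    "weak_prob": 70.0,
    "weak_evalue": 1e-4,
    "species": 95.0,
    "genus": 70.0,
    "acr_a": 0.5,
    "acr_b": -5.0,
    "acr_maxlen": 200,
    "acr_mincover": 40.0,
    "acr_rescue_min": 2,
    "overlap_fraction": 0.5,
    "unique_flag": 25.0,
}

DEFAULT_CONFIG: dict[str, Any] = {
    "demo": True,
    "prefix": "Demo_P1",
    "genome": {"length": 40000, "gc": 0.5, "terminal_repeat": 77},
    "callers": list(DEFAULT_CALLERS),
    "caller_sensitivity": {
        "AMIGene": 0.92, "Glimmer": 0.72, "MetaGeneAnnotator": 0.94,
        "Phanotate": 0.98, "Prodigal": 0.95,
    },
    "caller_fp_rate": {
        "AMIGene": 0.02, "Glimmer": 0.35, "MetaGeneAnnotator": 0.03,
        "Phanotate": 0.30, "Prodigal": 0.03,
    },
    "start_jitter": 0.3,
    "included_callers": [
        "AMIGene", "MetaGeneAnnotator", "Phanotate", "Prodigal",
    ],
    "affiliated_fraction": 0.55,
    "thresholds": dict(DEFAULT_THRESHOLDS),
    "inputs": {},
}


class MissingInputError(PhagePipeError):
    """A configured input file does not exist (CLI exit code 2)."""


def load_config(path: Optional[str | Path] = None) -> dict[str, Any]:
    """Merge a user YAML config over the defaults and validate it."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        if not Path(path).exists():
            raise MissingInputError(str(path))
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, Mapping) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    validate_config(config)
    return config


def validate_config(config: Mapping[str, Any]) -> None:
    t = config["thresholds"]
    for key in ("species", "genus"):
        if not 0.0 < float(t[key]) <= 100.0:
            raise ConfigurationError(
                f"threshold {key}={t[key]} outside (0, 100]"
            )
    if not 0.0 < float(t["overlap_fraction"]) <= 1.0:
        raise ConfigurationError(
            f"overlap_fraction={t['overlap_fraction']} outside (0, 1]"
        )
    if int(t["acr_maxlen"]) <= 0:
        raise ConfigurationError("acr_maxlen must be positive")
    included = config["included_callers"]
    if not included or not set(included) <= set(config["callers"]):
        raise ConfigurationError(
            "included_callers must be a non-empty subset of callers"
        )


def config_hash(config: Mapping[str, Any]) -> str:
    dumped = yaml.safe_dump(dict(config), sort_keys=True)
    return hashlib.sha256(dumped.encode()).hexdigest()


def _require_input(config: Mapping[str, Any], key: str) -> Path:
    path = config.get("inputs", {}).get(key)
    if not path or not Path(path).exists():
        raise MissingInputError(f"inputs.{key}: {path}")
    return Path(path)


class PipelineRun:
    """Lazily computed pipeline state for one config + seed."""

    def __init__(self, config: Mapping[str, Any], seed: int):
        validate_config(config)
        self.config = config
        self.seed = int(seed)
        self._cache: dict[str, Any] = {}

    # -- inputs -----------------------------------------------------------

    def genome_and_truth(self):
        if "genome" not in self._cache:
            if self.config["demo"]:
                g = self.config["genome"]
                genome, truth = synthetic_data.make_genome(
                    length=int(g["length"]), gc=float(g["gc"]),
                    terminal_repeat=int(g["terminal_repeat"]), seed=self.seed,
                )
            else:
                genomes = read_genomes_fasta(_require_input(self.config, "fasta"))
                genome, truth = genomes[0], None
            self._cache["genome"] = (genome, truth)
        return self._cache["genome"]

    def layout(self):
        """Trim the terminal repeat from the assembled contig."""
        if "layout" not in self._cache:
            genome, truth = self.genome_and_truth()
            trimmed, r = genome_layout.trim_terminal_repeat(genome)
            self._cache["layout"] = (trimmed, r, truth)
        return self._cache["layout"]

    def caller_predictions(self):
        if "predictions" not in self._cache:
            trimmed, _r, truth = self.layout()
            if self.config["demo"]:
                preds = synthetic_data.make_caller_outputs(
                    truth, trimmed.length,
                    callers=self.config["callers"],
                    sensitivity=self.config["caller_sensitivity"],
                    fp_rate=self.config["caller_fp_rate"],
                    start_jitter=float(self.config["start_jitter"]),
                    seed=self.seed + 1,
                    genome_id=trimmed.id,
                )
            else:
                paths = self.config.get("inputs", {}).get("predictions", {})
                preds = {}
                for caller in self.config["callers"]:
                    if caller not in paths or not Path(paths[caller]).exists():
                        raise MissingInputError(
                            f"inputs.predictions.{caller}: {paths.get(caller)}"
                        )
                    dialect = "gff3" if str(paths[caller]).endswith(".gff3") else "tsv"
                    preds[caller] = read_caller_predictions(
                        paths[caller], dialect, caller
                    )
            self._cache["predictions"] = preds
        return self._cache["predictions"]

    # -- consensus --------------------------------------------------------

    def consensus(self):
        if "consensus" not in self._cache:
            trimmed, _r, _truth = self.layout()
            preds = self.caller_predictions()
            merged = merge_predictions(
                [p for plist in preds.values() for p in plist],
                self.config["callers"],
                genome_length=trimmed.length,
            )
            stats = agreement_stats(merged, self.config["callers"])
            flags = flag_outlier_callers(
                stats, float(self.config["thresholds"]["unique_flag"])
            )
            kept = consensus_keep_policy(
                merged, self.config["included_callers"]
            )
            self._cache["consensus"] = (merged, stats, flags, kept)
        return self._cache["consensus"]

    # -- annotation -------------------------------------------------------

    def assignments(self):
        if "assignments" not in self._cache:
            _m, _s, _f, kept = self.consensus()
            ids = [orf_feature_id(o) for o in kept]
            t = self.config["thresholds"]
            if self.config["demo"]:
                hits = synthetic_data.make_hit_table(
                    ids, float(self.config["affiliated_fraction"]),
                    seed=self.seed + 2,
                )
            else:
                hits = read_hit_table(
                    _require_input(self.config, "phrog_hits"), "phrog"
                )
            by_query: dict[str, list] = {}
            for h in hits:
                by_query.setdefault(h.query_id, []).append(h)
            assignments = {
                oid: assign_phrog(
                    select_best_hit(by_query.get(oid, [])),
                    query_id=oid,
                    prob_min=float(t["phrog_prob"]),
                    evalue_max=float(t["phrog_evalue"]),
                )
                for oid in ids
            }
            overlay = ReannotationTable.packaged_default()
            updated = apply_reannotation(list(assignments.values()), overlay)
            self._cache["assignments"] = {a.query_id: a for a in updated}
        return self._cache["assignments"]

    # -- curation ---------------------------------------------------------

    def curation(self):
        if "curation" not in self._cache:
            trimmed, _r, _truth = self.layout()
            _m, _s, _f, kept = self.consensus()
            t = self.config["thresholds"]
            kept_orfs, decisions = curate_genome(
                kept, self.trnas(), self.assignments(),
                min_fraction=float(t["overlap_fraction"]),
                weak_prob_max=float(t["weak_prob"]),
                weak_evalue_min=float(t["weak_evalue"]),
                genome_length=trimmed.length,
                circular=trimmed.topology == "circular-permuted",
            )
            self._cache["curation"] = (kept_orfs, decisions)
        return self._cache["curation"]

    def trnas(self):
        return []  # demo genomes carry no tRNAs; file inputs could add them

    # -- final annotation -------------------------------------------------

    def annotation(self):
        if "annotation" not in self._cache:
            trimmed, _r, truth = self.layout()
            kept_orfs, decisions = self.curation()
            _m, _s, _f, pre_curation = self.consensus()
            discarded = [
                o for o in pre_curation
                if orf_feature_id(o)
                not in {orf_feature_id(k) for k in kept_orfs}
            ]
            genome, orfs, trnas = trimmed, list(kept_orfs), list(self.trnas())
            assignments = dict(self.assignments())
            decisions = list(decisions)
            if truth is not None and trimmed.topology == "circular-permuted":
                term = next(
                    t for t in truth if t.label == "terminase small subunit"
                )
                anchor = (term.strand, (term.stop_anchor() - 1) % trimmed.length + 1)
                match = [
                    o for o in orfs
                    if (o.strand, o.stop_anchor) == anchor
                ]
                if match:
                    term_id = orf_feature_id(match[0])
                    before = orfs + discarded
                    genome, oriented, trnas = genome_layout.orient_genome(
                        trimmed, before, term_id, trnas
                    )
                    n_kept = len(orfs)
                    # feature ids are coordinate-derived: remap keys through
                    # the orientation so assignments and decisions follow
                    id_map = {
                        orf_feature_id(old): orf_feature_id(new)
                        for old, new in zip(before, oriented)
                    }
                    assignments = {
                        id_map.get(oid, oid): a
                        for oid, a in assignments.items()
                    }
                    from dataclasses import replace as _replace
                    decisions = [
                        _replace(d, feature_id=id_map.get(d.feature_id, d.feature_id))
                        for d in decisions
                    ]
                    orfs = oriented[:n_kept]
                    discarded = oriented[n_kept:]
            ann = genome_layout.build_annotation(
                genome, orfs, trnas, assignments, decisions,
                discarded_orfs=discarded, prefix=self.config["prefix"],
            )
            self._cache["annotation"] = ann
        return self._cache["annotation"]

    # -- independent tables ----------------------------------------------

    def lifestyle_calls(self):
        if self.config["demo"] or "markers" not in self.config.get("inputs", {}):
            content = synthetic_data.load_marker_content()
        else:
            raise NotImplementedError("external marker tables not wired")
        return [
            classification.classify_lifestyle(gid, assigns)
            for gid, assigns in sorted(content.items())
        ]

    def clusters(self):
        t = self.config["thresholds"]
        if self.config["demo"]:
            matrix, _sp, _ge = synthetic_data.make_similarity_matrix(
                seed=self.seed + 3
            )
        else:
            matrix = read_similarity_matrix(
                _require_input(self.config, "similarity")
            )
        return classification.cluster_genomes(
            matrix, float(t["species"]), float(t["genus"])
        )

    def acr_calls(self):
        t = self.config["thresholds"]
        candidates = synthetic_data.load_acr_candidates()
        if self.config["demo"]:
            candidates = candidates + synthetic_data.acr_distractors()
        calls = acr_screen.filter_candidates(
            candidates,
            a_min=float(t["acr_a"]), b_min=float(t["acr_b"]),
            max_len=int(t["acr_maxlen"]), min_cover=float(t["acr_mincover"]),
        )
        return acr_screen.rescue_by_genus_consistency(
            calls, int(t["acr_rescue_min"])
        )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_all(
    config: Mapping[str, Any], seed: int, outdir: str | Path
) -> dict[str, Any]:
    """Run every stage and write the seven output tables plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config, seed)

    _merged, stats, flags, _kept = run.consensus()
    flag_by_caller = {c: flagged for c, _f, flagged in flags}
    _write_tsv(
        outdir / "agreement.tsv",
        ["subset", "count"],
        [
            [",".join(sorted(sub)), n]
            for sub, n in sorted(
                stats.per_subset_counts.items(), key=lambda kv: sorted(kv[0])
            )
            if n > 0
        ]
        + [["__union__", stats.n_union]]
        + [
            [f"__unique_pct__{c}",
             f"{stats.unique_percent(c):.1f}|flagged={flag_by_caller[c]}"]
            for c in stats.callers
        ],
    )

    ann = run.annotation()
    write_annotation(ann, outdir / f"{ann.genome_id}.gff3", "gff3")
    write_annotation(ann, outdir / "audit.tsv", "tsv")

    kept_curated, _decisions = run.curation()
    kept_ids = {orf_feature_id(o) for o in kept_curated}
    summary = summarize_annotation(
        [a for oid, a in sorted(run.assignments().items()) if oid in kept_ids]
    )
    _write_tsv(
        outdir / "summary.tsv",
        ["genome_id", "n_orfs", "pct_unknown_function", "pct_singleton"],
        [[ann.genome_id, summary.n_orfs, summary.pct_unknown_function,
          summary.pct_singleton]],
    )

    _write_tsv(
        outdir / "lifestyle.tsv",
        ["genome_id", "call", "markers", "rationale"],
        [
            [c.genome_id, c.call,
             ";".join(f"{f}:{r}" for f, r in c.markers_found), c.rationale]
            for c in run.lifestyle_calls()
        ],
    )

    _write_tsv(
        outdir / "clusters.tsv",
        ["level", "threshold", "members"],
        [
            [c.level, c.threshold_used, ",".join(c.members)]
            for c in run.clusters()
        ],
    )

    _write_tsv(
        outdir / "acr.tsv",
        ["genome_id", "genus", "protein_id", "family_id", "length_aa",
         "score_a", "score_b", "retained", "reasons"],
        [
            [x.candidate.genome_id, x.candidate.genus, x.candidate.protein_id,
             x.candidate.family_id, x.candidate.length_aa,
             x.candidate.score_a, x.candidate.score_b,
             x.retained, ",".join(x.reasons)]
            for x in run.acr_calls()
        ],
    )

    manifest = {
        "config_sha256": config_hash(config),
        "seed": int(seed),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
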