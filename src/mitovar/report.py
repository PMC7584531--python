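"""Report assembly: the pipeline's output tables and the run orchestrator.

Tables mirror the layouts of a whole-mtDNA case-control study report:
haplogroup distribution, per-SNV association, transition/transversion
per region, rare-variant comparison with rare/common shares,
non-synonymous/synonymous ratios, and the variant-load summary. All
tables are emitted as TSV with a header comment recording the tool
version and a hash of the run configuration; two runs with the same
configuration and seed produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .burden import (
    CarrierPredicate,
    DEFAULT_EXCLUSIONS,
    carrier_table,
    compare_burden,
    rarity_spectrum,
    tally,
    ts_tv_ratio,
)
from .cohort import (
    Cohort,
    FrequencyTable,
    PRIMARY_MUTATION,
    annotate_cohort,
    heteroplasmy_status,
    load_association_list,
    read_cohort_tsv,
    read_cohort_vcf,
)
from .haplotree import assign_cohort, default_ignore_list, default_tree, load_tree, load_ignore_list
from .reference import CODING_REGIONS, REGIONS, default_gene_model, load_gene_model
from .stats import ContingencyTable2x2, associate
from .synthetic import paper_fixture
from .variant_load import ScoreTable, compare_loads

logger = logging.getLogger(__name__)

_NA = "n/a"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _fmt(x, nd=3):
    return _NA if x is None else f"{x:.{nd}f}"


def _assoc_columns(res) -> dict:
    return {
        "p": round(res.p_value, 3),
        "OR": round(res.odds_ratio, 3),
        "ci_low": round(res.ci_low, 3),
        "ci_high": round(res.ci_high, 3),
        "haldane": res.haldane_applied,
    }


def haplogroup_distribution_table(cohort: Cohort) -> pd.DataFrame:
    """Per-haplogroup prevalence and association (distribution-table layout).

    Requires subjects to carry haplogroup calls (see
    :func:`mitovar.haplotree.assign_cohort`).
    """
    n_p, n_c = cohort.n_patients, cohort.n_controls
    counts: dict[str, dict[str, int]] = {}
    for s in cohort:
        if s.haplogroup is None:
            raise PipelineError("haplogroup", f"subject {s.subject_id} uncalled")
        counts.setdefault(s.haplogroup.haplogroup, {"patient": 0, "control": 0})
        counts[s.haplogroup.haplogroup][s.group] += 1
    rows = []
    for hg in sorted(counts):
        a, c = counts[hg]["patient"], counts[hg]["control"]
        res = associate(ContingencyTable2x2(a, n_p - a, c, n_c - c))
        rows.append({
            "haplogroup": hg,
            "patient_pct": round(100 * a / n_p),
            "control_pct": round(100 * c / n_c),
            **_assoc_columns(res),
        })
    return pd.DataFrame(rows)


def snv_association_table(cohort: Cohort, min_carriers: int = 1,
                          exclude=frozenset({PRIMARY_MUTATION})) -> pd.DataFrame:
    """Per-SNV carrier association scan (per-variant-table layout).

    One row per distinct (position, alt) carried by at least
    ``min_carriers`` subjects overall; the primary mutation is excluded
    (present in every patient by ascertainment)."""
    n_p, n_c = cohort.n_patients, cohort.n_controls
    carriers: dict[tuple[int, str], dict] = {}
    for s in cohort:
        for v in s:
            if v.key in exclude:
                continue
            entry = carriers.setdefault(
                v.key, {"variant": v, "patient": 0, "control": 0}
            )
            entry[s.group] += 1
    rows = []
    for key in sorted(carriers):
        entry = carriers[key]
        a, c = entry["patient"], entry["control"]
        if a + c < min_carriers:
            continue
        v = entry["variant"]
        res = associate(ContingencyTable2x2(a, n_p - a, c, n_c - c))
        effect = v.effect.protein_change if v.effect else ""
        rows.append({
            "variant": v.label,
            "locus": v.effect.locus if v.effect else "",
            "region": v.region or "",
            "effect": effect or (v.effect.category if v.effect else ""),
            "patient_pct": round(100 * a / n_p),
            "control_pct": round(100 * c / n_c),
            **_assoc_columns(res),
        })
    return pd.DataFrame(rows)


def tstv_table(cohort: Cohort) -> pd.DataFrame:
    """Transitions, transversions and their ratio per region and group."""
    scopes = list(REGIONS) + ["overall", "overall_unique"]
    rows = []
    for scope in scopes:
        mode = "unique" if scope == "overall_unique" else "occurrence"
        region = "overall" if scope.startswith("overall") else scope
        b = tally(cohort, region, mode)
        bp, bc = b["patient"], b["control"]
        row = {
            "region": scope,
            "patient_ts": bp.ts, "patient_tv": bp.tv,
            "patient_ratio": _fmt(ts_tv_ratio(bp), 2),
            "control_ts": bc.ts, "control_tv": bc.tv,
            "control_ratio": _fmt(ts_tv_ratio(bc), 2),
        }
        if bp.tv == 0 and bc.tv == 0:
            row.update({"p": _NA, "OR": _NA, "ci_low": _NA, "ci_high": _NA,
                        "haldane": _NA})
        else:
            row.update(_assoc_columns(compare_burden(bp, bc, "ts_vs_tv")))
        rows.append(row)
    return pd.DataFrame(rows)


def rare_variant_table(cohort: Cohort) -> pd.DataFrame:
    """Rare (≤cutoff) vs common frequency comparison per region, with
    the per-group rare/common shares used for the spectrum figure."""
    scopes = list(REGIONS) + ["overall", "overall_unique"]
    rows = []
    for scope in scopes:
        mode = "unique" if scope == "overall_unique" else "occurrence"
        region = "overall" if scope.startswith("overall") else scope
        b = tally(cohort, region, mode)
        spec = rarity_spectrum(cohort, region, mode)
        bp, bc = b["patient"], b["control"]
        row = {
            "region": scope,
            "patient_rare_share": _fmt(spec["patient"]["rare_share"], 3),
            "control_rare_share": _fmt(spec["control"]["rare_share"], 3),
            "patient_unknown": bp.unknown_rarity,
            "control_unknown": bc.unknown_rarity,
        }
        if (bp.rare + bp.common) == 0 and (bc.rare + bc.common) == 0:
            row.update({"p": _NA, "OR": _NA, "ci_low": _NA, "ci_high": _NA,
                        "haldane": _NA})
        else:
            row.update(_assoc_columns(compare_burden(bp, bc, "rare_vs_common")))
        rows.append(row)
    return pd.DataFrame(rows)


def nss_table(cohort: Cohort) -> pd.DataFrame:
    """Non-synonymous / synonymous counts and ratios per coding region."""
    scopes = sorted(CODING_REGIONS, key=list(REGIONS).index)
    scopes += ["overall", "overall_unique"]
    rows = []
    for scope in scopes:
        mode = "unique" if scope == "overall_unique" else "occurrence"
        region = "overall" if scope.startswith("overall") else scope
        b = tally(cohort, region, mode)
        bp, bc = b["patient"], b["control"]
        row = {
            "region": scope,
            "patient_ns": bp.ns, "patient_s": bp.s,
            "patient_ratio": _fmt(bp.ns / bp.s if bp.s else None, 2),
            "control_ns": bc.ns, "control_s": bc.s,
            "control_ratio": _fmt(bc.ns / bc.s if bc.s else None, 2),
        }
        if (bp.ns + bp.s) == 0 and (bc.ns + bc.s) == 0:
            row.update({"p": _NA, "OR": _NA, "ci_low": _NA, "ci_high": _NA,
                        "haldane": _NA})
        else:
            row.update(_assoc_columns(compare_burden(bp, bc, "ns_vs_s")))
        rows.append(row)
    return pd.DataFrame(rows)


def annotated_variant_table(cohort: Cohort,
                            homoplasmy_threshold: float = 95.0) -> pd.DataFrame:
    """Long-format per-subject per-variant annotation dump."""
    rows = []
    for s in cohort:
        for v in sorted(s, key=lambda v: v.key):
            rows.append({
                "subject_id": s.subject_id,
                "group": s.group,
                "variant": v.label,
                "locus": v.effect.locus if v.effect else "",
                "region": v.region or "",
                "effect": (v.effect.protein_change or v.effect.category)
                          if v.effect else "",
                "heteroplasmy_pct": v.heteroplasmy_fraction,
                "heteroplasmy_status": heteroplasmy_status(
                    v, homoplasmy_threshold),
                "population_freq_pct": v.population_frequency,
                "rarity": v.rarity,
                "reported_association": v.reported_association or "",
            })
    return pd.DataFrame(rows)


def load_report_table(cohort: Cohort, scores: ScoreTable,
                      threshold: float = 0.5, equal_var: bool = True
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-subject loads, group-summary block) for the variant loads."""
    cmp = compare_loads(cohort, scores, threshold, equal_var=equal_var)
    per_subject = pd.DataFrame([asdict(r) for r in cmp.per_subject])
    groups = ("patient", "control")
    summary = pd.DataFrame([
        {"load": "total",
         **{f"{g}_mean": round(cmp.mean_total[g], 3) for g in groups},
         **{f"{g}_sd": round(cmp.sd_total[g], 3) for g in groups},
         "t": round(cmp.t_total[0], 3), "df": cmp.t_total[1],
         "p": round(cmp.t_total[2], 3)},
        {"load": f"threshold>{threshold}",
         **{f"{g}_mean": round(cmp.mean_threshold[g], 3) for g in groups},
         **{f"{g}_sd": round(cmp.sd_threshold[g], 3) for g in groups},
         "t": round(cmp.t_threshold[0], 3), "df": cmp.t_threshold[1],
         "p": round(cmp.t_threshold[2], 3)},
    ])
    return per_subject, summary


def fixture_report() -> pd.DataFrame:
    """Association statistics recomputed on the 2x2 tables reconstructed
    from the published group sizes and printed frequencies."""
    fx = paper_fixture()
    rows = []
    for name, entry in fx.tables.items():
        res = associate(entry.table)
        rows.append({
            "table": name,
            "a": entry.table.a, "b": entry.table.b,
            "c": entry.table.c, "d": entry.table.d,
            **_assoc_columns(res),
            "printed_OR": entry.expected["OR"],
            "printed_p": entry.expected["p"],
        })
    return pd.DataFrame(rows)


# -- orchestration ----------------------------------------------------

@dataclass
class RunConfig:
    cohort_path: str
    frequency_path: str | None = None
    tree_path: str | None = None
    ignore_path: str | None = None
    scores_path: str | None = None
    association_path: str | None = None
    annotation_path: str | None = None
    fasta_path: str | None = None
    rarity_cutoff: float = 0.5
    score_threshold: float = 0.5
    homoplasmy_threshold: float = 95.0
    equal_var: bool = True
    out_dir: str = "mitovar_out"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rarity_cutoff <= 100:
            raise ValueError("rarity cutoff must be in (0,100]")
        if not 0 <= self.score_threshold <= 1:
            raise ValueError("score threshold must be in [0,1]")
        if not 0 < self.homoplasmy_threshold <= 100:
            raise ValueError("homoplasmy threshold must be in (0,100]")

    def digest(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mitovar {__version__} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_cohort_any(path: str | Path) -> Cohort:
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_cohort_vcf(path)
    return read_cohort_tsv(path)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run annotation, haplogrouping, association, burden and load
    stages end to end; returns a manifest of written files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mitovar")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict[str, str] = {}

    def stage(name, fn):
        logger.info("stage %s started", name)
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            logger.error("stage %s failed: %s", name, exc)
            if manifest:
                logger.error("partial outputs present: %s", sorted(manifest))
            raise PipelineError(name, str(exc)) from exc
        logger.info("stage %s done", name)
        return result

    def emit(name, df):
        path = out / f"{name}.tsv"
        _write_table(df, path, digest)
        manifest[name] = str(path)

    try:
        cohort = stage("read-cohort", lambda: read_cohort_any(config.cohort_path))
        if config.annotation_path or config.fasta_path:
            if not (config.annotation_path and config.fasta_path):
                raise PipelineError(
                    "reference", "annotation and FASTA must be given together")
            model = stage("reference", lambda: load_gene_model(
                config.annotation_path, config.fasta_path))
        else:
            model = stage("reference", default_gene_model)

        if config.frequency_path is None:
            raise PipelineError(
                "frequency", "rarity analysis requested but no frequency table")
        freq = stage("frequency",
                     lambda: FrequencyTable.from_tsv(config.frequency_path))
        assoc = (load_association_list(config.association_path)
                 if config.association_path else None)
        stage("annotate", lambda: annotate_cohort(
            cohort, model, freq, config.rarity_cutoff, assoc))
        emit("annotated_cohort",
             annotated_variant_table(cohort, config.homoplasmy_threshold))

        tree = (load_tree(config.tree_path) if config.tree_path
                else default_tree())
        ignore = (load_ignore_list(config.ignore_path) if config.ignore_path
                  else default_ignore_list())
        stage("haplogroup", lambda: assign_cohort(cohort, tree, ignore=ignore))
        emit("haplogroup_distribution", haplogroup_distribution_table(cohort))

        emit("snv_association", stage(
            "associate", lambda: snv_association_table(cohort)))
        emit("tstv", stage("burden-tstv", lambda: tstv_table(cohort)))
        emit("rare_variants", stage(
            "burden-rare", lambda: rare_variant_table(cohort)))
        emit("ns_s", stage("burden-nss", lambda: nss_table(cohort)))

        if config.scores_path:
            scores = stage("scores",
                           lambda: ScoreTable.from_tsv(config.scores_path))
            per_subject, summary = stage("load", lambda: load_report_table(
                cohort, scores, config.score_threshold, config.equal_var))
            emit("variant_load_subjects", per_subject)
            emit("variant_load_summary", summary)
            pred = CarrierPredicate(score_threshold=config.score_threshold)
            t = carrier_table(cohort, pred, scores)
            emit("score_carriers", pd.DataFrame([{
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                **_assoc_columns(associate(t)),
            }]))

        manifest["log"] = str(log_path)
        (out / "manifest.json").write_text(
            json.dumps({"version": __version__, "config_hash": digest,
                        "files": manifest}, indent=2, sort_keys=True) + "\n")
        manifest["manifest"] = str(out / "manifest.json")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
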