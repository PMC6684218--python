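"""End-to-end orchestration: corpus → tag → normalize → PRR → calibrate → timeline.

A :class:`PipelineConfig` names every input (posts, drug aliases, expanded
lexicon, known associations, manual exclusions, literature events), the
target drugs or drug classes, the comparison drugs, and either a serialized
tagger model or a gold-span file that bypasses tagging.  The run writes all
intermediate tables as plain TSV plus a JSON manifest with the record
cardinality at every stage, and is deterministic: the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .corpus import (
    DrugCorpus,
    build_drug_corpus,
    compile_drug_matcher,
    load_alias_table,
    merge_corpora,
    read_posts,
)
from .ner import EntitySpan, TaggerModel, read_standoff, tag_post, write_standoff
from .normalize import build_index, load_lexicon, normalize_mention
from .stats import (
    PairRecord,
    aggregate_counts,
    build_negative_controls,
    calibrate_threshold,
    compute_prr,
    flag_signals,
    load_known_associations,
    write_pair_records,
    write_signal_table,
)
from .timeline import lead_table, load_literature_events

__all__ = ["PipelineConfig", "PipelineStageError", "RunReport", "run_pipeline", "load_config"]

#: group id given to extracted ADR mentions that match no lexicon concept;
#: they still count toward count(D) ("any ADR"), never toward a target group.
OTHER_GROUP = "_other"


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs up to that stage are on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    posts: Path
    aliases: Path
    lexicon: Path
    out_dir: Path
    targets: dict[str, list[str]]  # class id -> member drug ids
    comparison: list[str]
    posts_format: str = "jsonl"
    gold_spans: Path | None = None
    model: Path | None = None
    known_associations: Path | None = None
    manual_exclusions: Path | None = None
    literature: Path | None = None
    percentile: float = 95.0
    min_controls: int = 10
    seed: int = 0

    def validate(self) -> None:
        members = [d for drugs in self.targets.values() for d in drugs]
        if not members or not self.comparison:
            raise ValueError("need at least one target drug and one comparison drug")
        overlap = set(members) & set(self.comparison)
        if overlap:
            raise ValueError(f"drugs in both target and comparison sets: {sorted(overlap)}")
        if len(set(self.comparison)) != len(self.comparison):
            raise ValueError("duplicate comparison drugs")
        if (self.gold_spans is None) == (self.model is None):
            raise ValueError("exactly one of gold_spans or model must be given")
        for name in ("posts", "aliases", "lexicon", "gold_spans", "model",
                     "known_associations", "manual_exclusions", "literature"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; paths are relative to the file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    base = Path(path).resolve().parent

    def p(key: str) -> Path | None:
        return (base / raw[key]) if raw.get(key) else None

    return PipelineConfig(
        posts=p("posts"),
        aliases=p("aliases"),
        lexicon=p("lexicon"),
        out_dir=base / raw["out_dir"],
        targets={k: list(v) for k, v in raw["targets"].items()},
        comparison=list(raw["comparison"]),
        posts_format=raw.get("posts_format", "jsonl"),
        gold_spans=p("gold_spans"),
        model=p("model"),
        known_associations=p("known_associations"),
        manual_exclusions=p("manual_exclusions"),
        literature=p("literature"),
        percentile=float(raw.get("percentile", 95.0)),
        min_controls=int(raw.get("min_controls", 10)),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class RunReport:
    signals: list
    threshold: float
    controls: list[tuple[str, str]]
    control_prrs: dict[tuple[str, str], float]
    leads: list[dict]
    manifest: dict
    out_dir: Path


def _load_exclusions(path: Path | None) -> list[tuple[str, str, str]]:
    if path is None:
        return []
    rows = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"exclusion line {i}: expected 3 columns")
        rows.append((parts[0], parts[1], parts[2]))
    return rows


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full signal-generation pipeline and write its outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name: str):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
                raise PipelineStageError(name, exc) from exc
        return deco

    # -- corpus ------------------------------------------------------------
    @stage("corpus")
    def corpora() -> dict[str, DrugCorpus]:
        posts = read_posts(config.posts, format=config.posts_format)
        aliases = load_alias_table(config.aliases)
        units: dict[str, DrugCorpus] = {}
        for class_id, members in sorted(config.targets.items()):
            parts = [
                build_drug_corpus(posts, compile_drug_matcher(aliases[d]), d)
                for d in members
            ]
            units[class_id] = merge_corpora(parts, class_id)
        for drug in sorted(config.comparison):
            units[drug] = build_drug_corpus(
                posts, compile_drug_matcher(aliases[drug]), drug
            )
        manifest["stages"]["corpus"] = {
            "posts_in": len(posts),
            "corpus_sizes": {k: len(c) for k, c in sorted(units.items())},
        }
        return units

    post_lookup = {
        p.post_id: p for corpus in corpora.values() for p in corpus.posts
    }

    # -- tag ---------------------------------------------------------------
    @stage("tag")
    def spans() -> list[EntitySpan]:
        if config.gold_spans is not None:
            extracted = [
                s for s in read_standoff(config.gold_spans) if s.post_id in post_lookup
            ]
            mode = "gold"
        else:
            model = TaggerModel.load(config.model)
            extracted = []
            for post_id in sorted(post_lookup):
                extracted.extend(tag_post(model, post_lookup[post_id]))
            mode = "model"
        write_standoff(extracted, out / "spans.tsv")
        manifest["stages"]["tag"] = {
            "mode": mode,
            "spans": len(extracted),
            "adr_spans": sum(1 for s in extracted if s.label == "ADR"),
        }
        return extracted

    # -- normalize ---------------------------------------------------------
    @stage("normalize")
    def records() -> dict[str, list[PairRecord]]:
        index = build_index(load_lexicon(config.lexicon))
        cache: dict[str, str] = {}

        def group_of(surface: str) -> str:
            if surface not in cache:
                match = normalize_mention(surface, index)
                cache[surface] = match.group_id if match else OTHER_GROUP
            return cache[surface]

        spans_by_post: dict[str, list[EntitySpan]] = {}
        for s in spans:
            if s.label == "ADR":  # indications are never normalized
                spans_by_post.setdefault(s.post_id, []).append(s)
        by_unit: dict[str, list[PairRecord]] = {}
        for unit_id, corpus in sorted(corpora.items()):
            rows: list[PairRecord] = []
            for post in corpus.posts:
                seen_groups: set[str] = set()
                for s in spans_by_post.get(post.post_id, []):
                    group = group_of(s.surface)
                    if group in seen_groups:
                        continue
                    seen_groups.add(group)
                    rows.append(
                        PairRecord(
                            drug_id=unit_id,
                            group_id=group,
                            user_id=post.user_id,
                            post_id=post.post_id,
                            date=post.created_at,
                        )
                    )
            rows.sort(key=lambda r: (r.group_id, r.post_id))
            by_unit[unit_id] = rows
        all_rows = [r for unit in sorted(by_unit) for r in by_unit[unit]]
        write_pair_records(all_rows, out / "pair_records.tsv")
        manifest["stages"]["normalize"] = {
            "pair_records": len(all_rows),
            "normalized": sum(1 for r in all_rows if r.group_id != OTHER_GROUP),
        }
        return by_unit

    # target ADR groups are defined by the lexicon
    target_groups = sorted({e.group_id for e in load_lexicon(config.lexicon)})

    # -- calibrate ---------------------------------------------------------
    @stage("calibrate")
    def calibration():
        known = (
            load_known_associations(config.known_associations)
            if config.known_associations
            else None
        )
        exclusions = _load_exclusions(config.manual_exclusions)
        control_set = build_negative_controls(
            sorted(config.comparison), target_groups, known, exclusions
        )
        control_prrs: dict[tuple[str, str], float] = {}
        for drug, group in control_set.pairs:
            others = [d for d in config.comparison if d != drug]
            counts = aggregate_counts(
                records[drug],
                [r for d in others for r in records[d]],
                groups=[group],
            )[group]
            try:
                control_prrs[(drug, group)] = compute_prr(counts)
            except ZeroDivisionError:
                continue
        threshold = calibrate_threshold(
            list(control_prrs.values()),
            percentile=config.percentile,
            min_n=config.min_controls,
        )
        with (out / "controls.tsv").open("w", encoding="utf-8") as fh:
            fh.write("drug_id\tgroup_id\tprr\n")
            for (drug, group) in control_set.pairs:
                prr = control_prrs.get((drug, group))
                fh.write(f"{drug}\t{group}\t{'' if prr is None else f'{prr:.6f}'}\n")
        manifest["stages"]["calibrate"] = {
            "candidates": control_set.n_candidates,
            "after_known": control_set.n_after_known,
            "final_controls": control_set.n_final,
            "threshold": threshold,
            "percentile": config.percentile,
        }
        return control_set, control_prrs, threshold

    control_set, control_prrs, threshold = calibration

    # -- flag --------------------------------------------------------------
    @stage("flag")
    def signals():
        comparison_rows = [r for d in sorted(config.comparison) for r in records[d]]
        rows = []
        for class_id in sorted(config.targets):
            counts = aggregate_counts(
                records[class_id], comparison_rows, groups=target_groups
            )
            for group in target_groups:
                rows.append((class_id, group, counts[group]))
        flagged = flag_signals(rows, threshold)
        write_signal_table(flagged, out / "signals.tsv")
        manifest["stages"]["flag"] = {
            "pairs": len(flagged),
            "flagged": sum(1 for s in flagged if s.flagged),
        }
        return flagged

    # -- timeline ----------------------------------------------------------
    @stage("timeline")
    def leads():
        if config.literature is None:
            manifest["stages"]["timeline"] = {"pairs": 0}
            return []
        events = load_literature_events(config.literature)
        all_rows = [r for unit in sorted(records) for r in records[unit]]
        rows = lead_table(all_rows, events)
        with (out / "leads.tsv").open("w", encoding="utf-8") as fh:
            fh.write("drug_id\tgroup_id\tfirst_post\tfirst_literature\tlead_months\n")
            for row in rows:
                first = row["first_post"].isoformat() if row["first_post"] else ""
                lead = row["lead_months"] if row["lead_months"] is not None else ""
                fh.write(
                    f"{row['drug_id']}\t{row['group_id']}\t{first}"
                    f"\t{row['first_literature'].strftime('%Y-%m')}\t{lead}\n"
                )
        manifest["stages"]["timeline"] = {"pairs": len(rows)}
        return rows

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(
        signals=signals,
        threshold=threshold,
        controls=control_set.pairs,
        control_prrs=control_prrs,
        leads=leads,
        manifest=manifest,
        out_dir=out,
    )
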