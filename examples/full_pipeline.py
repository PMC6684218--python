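"""Run the full signal-generation pipeline end to end on generated data.

Writes a synthetic forum with one planted association plus all side inputs
(aliases, lexicon, known associations, manual exclusions, literature
dates) to a scratch directory, then executes corpus building, gold-span
extraction, normalization, counting, calibration, flagging and lead-time
analysis in one call, printing the resulting signal table.
"""

import tempfile
from pathlib import Path

from adrsignal.pipeline import PipelineConfig, run_pipeline
from adrsignal.synth import default_config, generate_corpus, generate_lexicon_fixture

TARGET, GROUP = "albanib", "hypohidrosis"
root = Path(tempfile.mkdtemp(prefix="adrsignal-demo-"))
config = default_config(n_users=2000, seed=5).plant(TARGET, GROUP, 0.24)
bundle = generate_corpus(config)
bundle.write(root)
generate_lexicon_fixture(root)
comparison = [d for d in config.drug_ids if d != TARGET]
(root / "known.tsv").write_text(f"{comparison[0]}\trash\tadr\n")
(root / "exclusions.tsv").write_text(f"{comparison[1]}\tacne\tsyndromic\n")
(root / "literature.tsv").write_text(f"{TARGET}\t{GROUP}\t2017-06\tcase report\tcase_report\n")

report = run_pipeline(
    PipelineConfig(
        posts=root / "posts.jsonl",
        aliases=root / "aliases.tsv",
        lexicon=root / "lexicon.tsv",
        out_dir=root / "out",
        targets={TARGET: [TARGET]},
        comparison=comparison,
        gold_spans=root / "gold_spans.tsv",
        known_associations=root / "known.tsv",
        manual_exclusions=root / "exclusions.tsv",
        literature=root / "literature.tsv",
    )
)

stages = report.manifest["stages"]
print(f"posts in: {stages['corpus']['posts_in']}; "
      f"spans: {stages['tag']['spans']}; "
      f"pair records: {stages['normalize']['pair_records']}")
print(f"controls: {stages['calibrate']['candidates']} candidates -> "
      f"{stages['calibrate']['final_controls']} after exclusions; "
      f"threshold {report.threshold:.3f}")
print(f"{'pair':30s} {'PRR':>7s}  flagged")
for s in sorted(report.signals, key=lambda s: -s.prr):
    print(f"{s.drug_id + ' / ' + s.group_id:30s} {s.prr:7.3f}  {s.flagged}")
for row in report.leads:
    print(f"lead time for {row['drug_id']}/{row['group_id']}: "
          f"{row['lead_months']} months before the literature report")
print(f"outputs written under {report.out_dir}")
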