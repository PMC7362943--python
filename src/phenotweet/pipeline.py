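"""End-to-end pipeline: lexicon → ingest → anchor → match → curate → history.

``run_pipeline`` wires all stages together for a directory of timeline
dumps, producing per-user H/M/D sets, anchors, patient histories, a
summary table, an audit log with one line per discarded tweet or match,
and a machine-readable run manifest.  Nothing is written until every
stage has succeeded, so a failing run leaves no partial outputs; identical
config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import yaml

from phenotweet.annotate import apply_curation, match_ontology, match_watchlist, read_curation
from phenotweet.history import (
    build_disease_set,
    build_history,
    export_history,
    merge_events,
    summarize_users,
    write_summary,
)
from phenotweet.ingest import (
    DEFAULT_DIAGNOSIS_PATTERNS,
    detect_diagnosis,
    filter_statuses,
    read_timeline,
    select_users,
)
from phenotweet.lexicon import DEFAULT_EXCLUSIONS, build_lexicon, load_watchlist


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (YAML-loadable)."""

    ontology: Path
    watchlist: Path
    timeline_dir: Path
    out_dir: Path
    disease: str
    aliases: tuple[str, ...] = ()
    decisions: Path | None = None
    dialect: str = "jsonl"
    patterns: tuple[str, ...] = DEFAULT_DIAGNOSIS_PATTERNS
    include_synonyms: bool = True
    substring: bool = False
    exclusions: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUSIONS))
    min_tweets: int = 100
    years: float = 5.0
    reference_date: date | None = None
    window_days: int = 7
    policy: str = "strict_M"

    def __post_init__(self) -> None:
        for name in ("ontology", "watchlist", "timeline_dir", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.decisions is not None:
            self.decisions = Path(self.decisions)
        if isinstance(self.reference_date, str):
            self.reference_date = date.fromisoformat(self.reference_date)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write the output directory.

    Returns the output directory path.  Raises :class:`PipelineError`
    naming the failing stage; on failure nothing is written.
    """
    for path, label in (
        (config.ontology, "ontology"),
        (config.watchlist, "watchlist"),
        (config.timeline_dir, "timeline_dir"),
    ):
        if not Path(path).exists():
            raise PipelineError(f"startup: missing {label} path {path}")
    audit: list[str] = []

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name}: {exc}") from exc

        return wrap

    lexicon = stage("lexicon")(
        build_lexicon, config.ontology, config.exclusions, config.include_synonyms
    )
    watchlist = stage("watchlist")(load_watchlist, config.watchlist)

    pattern = "*.csv" if config.dialect == "csv" else "*.jsonl"
    timeline_files = sorted(Path(config.timeline_dir).glob(pattern))
    if not timeline_files:
        raise PipelineError(
            f"ingest: no {pattern} files in {config.timeline_dir}"
        )
    timelines = [
        stage("ingest")(read_timeline, f, config.dialect) for f in timeline_files
    ]

    filtered = {}
    anchors = {}
    for tl in timelines:
        ftl = filter_statuses(tl)
        for t in tl:
            if t.is_retweet or t.is_reply:
                audit.append(
                    f"discard tweet {t.tweet_id} ({'retweet' if t.is_retweet else 'reply'})"
                )
        filtered[tl.user_id] = ftl
        anchor = stage("anchor")(
            detect_diagnosis, ftl, [config.disease, *config.aliases], config.patterns
        )
        if anchor is None:
            audit.append(f"user {tl.user_id}: no diagnosis anchor")
        anchors[tl.user_id] = anchor

    selected = stage("select")(
        select_users,
        timelines,
        [a for a in anchors.values() if a is not None],
        config.min_tweets,
        config.years,
        config.reference_date,
    )
    for tl in timelines:
        if tl.user_id not in selected:
            audit.append(f"user {tl.user_id}: excluded by selection criteria")

    decisions = (
        stage("curate")(read_curation, config.decisions)
        if config.decisions is not None
        else []
    )

    results = {}
    for uid in selected:
        ftl = filtered[uid]
        anchor = anchors[uid]
        hpo = stage("match")(match_ontology, ftl, lexicon, config.substring)
        wl = stage("match")(match_watchlist, ftl, watchlist, config.substring)
        matches = hpo + wl
        match_ids = {m.match_id for m in matches}
        user_decisions = [d for d in decisions if d.match_id in match_ids]
        h_set, m_set = stage("curate")(
            apply_curation, matches, user_decisions, config.policy, uid
        )
        kept_ids = {m.match_id for m in h_set.matches + m_set.matches}
        for m in matches:
            if m.match_id not in kept_ids:
                audit.append(f"discard match {m.match_id}")
        d_set = stage("history")(build_disease_set, h_set, m_set, ftl)
        events = stage("history")(
            merge_events,
            d_set,
            anchor,
            ftl,
            config.window_days,
            user_decisions,
            lexicon.labels,
        )
        history = build_history(uid, anchor, events)
        results[uid] = (ftl, anchor, h_set, m_set, d_set, history)

    summary = summarize_users(
        [(uid, r[0], r[2], r[3]) for uid, r in results.items()]
    )

    # All stages succeeded; only now touch the filesystem.
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "histories").mkdir(exist_ok=True)
    anchors_payload = {
        uid: None
        if a is None
        else {
            "disease": a.disease,
            "anchor_date": a.anchor_date.isoformat(),
            "tweet_id": a.tweet_id,
            "pattern": a.pattern,
        }
        for uid, a in anchors.items()
    }
    (out / "anchors.json").write_text(
        json.dumps(anchors_payload, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    sets_payload = {
        uid: {
            "H": list(r[2].tweet_ids),
            "M": list(r[3].tweet_ids),
            "D": list(r[4].tweet_ids),
        }
        for uid, r in results.items()
    }
    (out / "sets.json").write_text(
        json.dumps(sets_payload, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    for uid, r in results.items():
        export_history(r[5], out / "histories" / f"{uid}.json", "json")
        export_history(r[5], out / "histories" / f"{uid}.tsv", "tsv")
    write_summary(summary, out / "summary.tsv")
    (out / "run.log").write_text("".join(f"{line}\n" for line in audit), encoding="utf-8")

    from phenotweet import __version__ as version

    manifest = {
        "version": version,
        "config": {
            k: str(v) if isinstance(v, (Path, date)) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {
            "ontology": _sha256(config.ontology),
            "watchlist": _sha256(config.watchlist),
            "timelines": {f.name: _sha256(f) for f in timeline_files},
            "decisions": _sha256(config.decisions) if config.decisions else None,
        },
        "selected_users": list(selected),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out
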