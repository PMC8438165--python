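"""End-to-end orchestration: corpus → pre-processing → all analyses.

One config drives every stage on the SAME pre-processed corpus, so the
phonotactic, surprisal and lexical analyses see identical surface forms.
Outputs are UTF-8 TSVs plus a manifest carrying the config hash, seed and
per-stage row counts; reruns with the same config produce identical
bundles.  A stage failure aborts the run, removes partial outputs, and
names the failing stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import alternations as alt
from . import phonotactics as pt
from . import surprisal as sp
from .corpus import (
    Corpus,
    apply_deletion,
    collapse_palatalization,
    phone_streams,
    read_corpus,
    write_corpus,
)
from .lexicon import build_lexicon, lexicon_frame, variation_summary
from .synthesis import SyntheticConfig, generate_corpus

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Exactly one corpus source: a corpus file or a synthetic config."""

    corpus_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    deletion_rate: float = 0.10  # applied to file corpora during pre-processing
    deletion_seed: int = 1
    boundaries: bool = True
    theta_under: float = 0.75
    theta_over: float = 1.25
    top_k_constraints: int = 5
    top_k_vowels: int = 3
    min_phrases_for_phrase_stats: int = 100
    out_dir: str = "results/run"

    def validate(self) -> None:
        if (self.corpus_path is None) == (self.synthetic is None):
            raise ValueError("exactly one corpus source required "
                             "(corpus_path or synthetic)")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = dataclasses.asdict(self.synthetic)
            syn["pos_labels"] = list(syn["pos_labels"])
            d["synthetic"] = syn
        return d

    def config_hash(self) -> str:
        # out_dir is where results land, not an input to the computation
        d = self.to_jsonable()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "pos_labels" in syn:
                syn["pos_labels"] = tuple(syn["pos_labels"])
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def _write_tsv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(frame)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "seed": (config.synthetic.seed if config.synthetic is not None
                 else config.deletion_seed),
        "stages": {},
        "degenerate_phrase_stats": False,
    }

    def track(path: Path) -> Path:
        written.append(path)
        return path

    stage = "source"
    try:
        # -- source -------------------------------------------------------
        if config.synthetic is not None:
            corpus, _truth = generate_corpus(config.synthetic)
            manifest["stages"]["source"] = {"kind": "synthetic",
                                            "n_phrases": len(corpus)}
        else:
            corpus = read_corpus(config.corpus_path)
            manifest["stages"]["source"] = {"kind": "file",
                                            "path": config.corpus_path,
                                            "n_phrases": len(corpus)}

        # -- preprocess ---------------------------------------------------
        stage = "preprocess"
        if config.synthetic is None:
            corpus = collapse_palatalization(corpus)
            corpus = apply_deletion(corpus, config.deletion_rate,
                                    config.deletion_seed)
        # synthetic corpora come out of the generator already pre-processed
        corpus_path = track(out / "corpus.jsonl")
        write_corpus(corpus, corpus_path)
        manifest["stages"]["preprocess"] = {
            "n_phrases": len(corpus), "n_words": corpus.n_words(),
            "n_phones": corpus.n_phones(), "files": ["corpus.jsonl"],
        }

        degenerate = len(corpus) < config.min_phrases_for_phrase_stats
        manifest["degenerate_phrase_stats"] = degenerate

        # -- phonotactics ---------------------------------------------------
        stage = "phonotactics"
        if degenerate:
            manifest["stages"]["phonotactics"] = {"skipped": "degenerate"}
            manifest["stages"]["surprisal"] = {"skipped": "degenerate"}
        else:
            streams = phone_streams(corpus, with_boundaries=config.boundaries)
            table = pt.count_biphones(streams)
            th = pt.Thresholds(config.theta_under, config.theta_over)
            constraints = pt.induce_constraints(table, th)
            n_bi = _write_tsv(pt.biphone_frame(table), track(out / "biphones.tsv"))
            cons_frame = pd.DataFrame(
                [{"kind": c.kind, "x": c.biphone[0], "y": c.biphone[1],
                  "strength": c.strength, "oe": c.oe}
                 for c in sorted(constraints,
                                 key=lambda c: (c.kind, -c.strength, c.biphone))],
                columns=["kind", "x", "y", "strength", "oe"],
            )
            n_cons = _write_tsv(cons_frame, track(out / "constraints.tsv"))
            manifest["stages"]["phonotactics"] = {
                "n_biphones": n_bi, "n_constraints": n_cons,
                "files": ["biphones.tsv", "constraints.tsv"],
            }

            # -- surprisal -------------------------------------------------
            stage = "surprisal"
            dist = sp.successor_distribution(streams)
            n_sur = _write_tsv(sp.surprisal_frame(dist),
                               track(out / "surprisal.tsv"))
            cons_contexts = sorted(
                c for c in dist.contexts()
                if c in corpus.inventory and corpus.inventory[c].is_consonant
            )
            n_cand = _write_tsv(
                sp.candidate_frame(dist, cons_contexts, k=config.top_k_vowels),
                track(out / "candidates.tsv"),
            )
            manifest["stages"]["surprisal"] = {
                "n_rows": n_sur, "n_contexts": n_cand,
                "files": ["surprisal.tsv", "candidates.tsv"],
            }

        # -- lexicon --------------------------------------------------------
        stage = "lexicon"
        lexicon = build_lexicon(corpus)
        n_lex = _write_tsv(lexicon_frame(lexicon), track(out / "lexicon.tsv"))
        summary = variation_summary(lexicon)
        manifest["stages"]["lexicon"] = {
            "n_rows": n_lex, "n_entries": summary.n_entries,
            "n_multiform": summary.n_multiform, "n_skipped": lexicon.n_skipped,
            "files": ["lexicon.tsv"],
        }

        # -- alternations ---------------------------------------------------
        stage = "alternations"
        table_a = alt.collect_operations(lexicon)
        n_ops = _write_tsv(alt.operations_frame(table_a),
                           track(out / "operations.tsv"))
        cons_ctx = sorted(
            c for c in table_a.contexts()
            if c in corpus.inventory and corpus.inventory[c].is_consonant
        )
        n_ztv = _write_tsv(
            alt.zero_to_vowel_report(table_a, k=config.top_k_vowels,
                                     contexts=cons_ctx),
            track(out / "zero_to_vowel.tsv"),
        )
        manifest["stages"]["alternations"] = {
            "n_rows": n_ops, "n_contexts": n_ztv,
            "files": ["operations.tsv", "zero_to_vowel.tsv"],
        }

    except Exception as exc:  # noqa: BLE001 - abort cleanly, name the stage
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n",
                             encoding="utf-8")
    logger.info("pipeline complete: %d stages, outputs in %s",
                len(manifest["stages"]), out)
    return manifest
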