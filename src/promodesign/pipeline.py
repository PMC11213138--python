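"""End-to-end workflow orchestration.

Five steps: (1) pretrain a backbone on related expression corpora;
(2) fine-tune conservative design models across an α sweep; (3) design
candidates by simplex gradient ascent from every starting sequence;
(4) score with the ensemble and greedily select the validation batch;
(5) evaluate — against the synthetic oracle in ``oracle`` mode (fresh
noisy "measurements" of the selected designs, percentile-calibrated
against the training batch), or stop after selection in ``data`` mode
where validation happens in the lab. Steps 2–5 can be repeated for
multi-round design, appending each round's measured designs to the panel.

Every stochastic step derives its seed from the run's master seed, and the
run manifest records the configuration, seeds, and step artifacts, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .calibration import CommonSet, improvement_report, percent_gain_best
from .conservative import InnerAscentConfig, train_alpha_sweep
from .designer import design_pool
from .ensemble import build_ensemble, filter_candidates, score_candidates, write_scores
from .model import ExpressionModel, ModelConfig, TrainConfig, pretrain, transfer
from .oracle import (MotifGrammar, Motif, SequencePanel, default_grammar,
                     generate_panel, measure_panel, true_de_batch)
from .selection import (SelectionConfig, diagnose_training_set, greedy_select,
                        write_selection)
from .seq_core import DnaSequence, read_sequence_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "DataError", "run_pipeline",
           "smoke_config", "pretraining_grammar"]


class ConfigError(ValueError):
    """Invalid run configuration (detected before any compute)."""


class DataError(ValueError):
    """Invalid or missing input data."""


@dataclass
class PipelineConfig:
    seed: int = 0
    mode: str = "oracle"                      # "oracle" | "data"
    length: int = 120
    cell_types: tuple[str, ...] = ("cellA", "cellB", "cellC")
    targets: tuple[str, ...] = ("cellA", "cellB")
    # oracle-mode data generation
    n_panel: int = 400
    planting_rate: float = 0.15
    noise_sd: float = 0.2
    pretrain_n: int = 800
    # data mode
    panel_tsv: str | None = None
    pretrain_tsv: tuple[str, ...] = ()
    # modelling
    arch: ModelConfig | None = None
    do_pretrain: bool = True
    pretrain_cfg: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr=3e-3, max_epochs=120, patience=25))
    train: TrainConfig = field(default_factory=TrainConfig)
    inner: InnerAscentConfig = field(default_factory=InnerAscentConfig)
    alphas: tuple[float, ...] = (0.0, 0.01)
    # scoring / selection
    ensemble_size: int = 3
    ensemble_split_seed: int = 101
    expression_quantile: float = 0.5
    K: int = 50
    beta: float = 0.0
    kmer_k: int = 6
    # evaluation
    common_set_size: int = 120
    rounds: int = 1

    def __post_init__(self):
        if self.mode not in ("oracle", "data"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "data" and not self.panel_tsv:
            raise ConfigError("data mode requires panel_tsv")
        unknown = set(self.targets) - set(self.cell_types)
        if unknown:
            raise ConfigError(f"targets not in cell-type panel: {sorted(unknown)}")
        if self.ensemble_split_seed == self.train.split_seed:
            raise ConfigError("ensemble_split_seed must differ from the "
                              "design models' split seed")
        if self.rounds < 1:
            raise ConfigError("rounds must be >= 1")

    # -- construction ---------------------------------------------------
    _NESTED = {"train": TrainConfig, "pretrain_cfg": TrainConfig,
               "inner": InnerAscentConfig, "arch": ModelConfig}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in cls._NESTED.items():
            if key in d and isinstance(d[key], dict):
                sub_known = {f.name for f in dataclasses.fields(sub)}
                bad = set(d[key]) - sub_known
                if bad:
                    raise ConfigError(f"unknown keys under {key!r}: {sorted(bad)}")
                try:
                    d[key] = sub(**d[key])
                except (TypeError, ValueError) as e:
                    raise ConfigError(f"invalid {key!r} section: {e}") from e
        for key in ("cell_types", "targets", "alphas", "pretrain_tsv"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        try:
            return cls(**d)
        except ConfigError:
            raise
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            return v

        return clean(dataclasses.asdict(self))


def smoke_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale end-to-end configuration: 400 fine-tuning sequences of
    120 bp, a 3,000-sequence pretraining corpus, 20 inner-ascent steps,
    two design models (α=0 and α=0.01), a 3-member ensemble, and a
    selected batch of 50."""
    return PipelineConfig(
        seed=seed, length=120, n_panel=400, pretrain_n=3000,
        train=TrainConfig(max_epochs=35, patience=10, lr=1e-3,
                          split_seed=0, seed=seed),
        inner=InnerAscentConfig(steps=20, mu_batch=32),
        alphas=(0.0, 0.01), ensemble_size=3, K=50,
    )


def pretraining_grammar(g: MotifGrammar, seed: int) -> MotifGrammar:
    """A related-context grammar for pretraining corpora: same motif
    vocabulary, different cell types with rotated private effects and
    uniform basal levels — large datasets from other cellular contexts
    that share regulatory features with the target panel."""
    cts = [f"pre{c}" for c in g.cell_types]
    n = len(g.cell_types)
    motifs = []
    for m in g.motifs:
        effs = [m.effects[c] for c in g.cell_types]
        if len(set(effs)) == 1:
            new_eff = {c: effs[0] for c in cts}
        else:
            rotated = effs[1:] + effs[:1]
            new_eff = {c: 0.8 * e for c, e in zip(cts, rotated)}
        motifs.append(Motif(m.name, m.pwm.copy(), new_eff))
    _ = n
    return MotifGrammar(cts, motifs, {c: 2.0 for c in cts},
                        noise_sd=g.noise_sd, seed=seed)


def _derive(seed: int, offset: int) -> int:
    return (seed * 9973 + offset) % (2 ** 31 - 1)


def _spaced_common_set(panel: SequencePanel, target: str, size: int
                       ) -> CommonSet:
    """Common-set sequences spanning the measured DE range of the target
    cell (evenly spaced ranks), so the calibration anchors cover the whole
    scale the designed sequences will be compared on."""
    order = np.argsort(panel.measured_de(target))
    take = np.unique(np.linspace(0, len(order) - 1,
                                 min(size, len(order))).astype(int))
    return CommonSet([panel.sequences[i].id for i in order[take]])


@dataclass
class TargetResult:
    target: str
    pool_size: int
    filtered_size: int
    fraction_improved: float | None
    percent_gain_best: float | None
    spearman_rho: float | None
    mean_true_de_selected: float | None
    mean_true_de_starts: float | None
    mean_entropy: float | None
    mean_hamming: float | None


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the workflow; returns the manifest dict (also written to
    ``out_dir/manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest: dict = {"version": _version, "seed": config.seed,
                      "config": config.to_dict(), "steps": [], "rounds": []}

    # ---- step 0: data -------------------------------------------------
    grammar = None
    if config.mode == "oracle":
        grammar = default_grammar(seed=_derive(config.seed, 1),
                                  noise_sd=config.noise_sd,
                                  cell_types=config.cell_types)
        panel = generate_panel(grammar, config.n_panel, config.length,
                               planting_rate=config.planting_rate,
                               seed=_derive(config.seed, 2))
        grammar.to_json(out / "grammar.json")
        pre_grammar = pretraining_grammar(grammar, _derive(config.seed, 3))
        corpora = [generate_panel(pre_grammar, config.pretrain_n,
                                  config.length,
                                  planting_rate=config.planting_rate,
                                  seed=_derive(config.seed, 4),
                                  id_prefix="pre")]
    else:
        try:
            seqs, expr = read_sequence_table(config.panel_tsv, config.length)
        except (OSError, ValueError) as e:
            raise DataError(f"cannot read panel table: {e}") from e
        if list(expr.columns) != list(config.cell_types):
            raise DataError("panel columns do not match configured cell types")
        panel = SequencePanel(seqs, expr.to_numpy(), list(config.cell_types))
        corpora = []
        for p in config.pretrain_tsv:
            s, e_ = read_sequence_table(p, config.length)
            corpora.append(SequencePanel(s, e_.to_numpy(), list(e_.columns)))
    panel.write(out / "panel.fasta", out / "panel.tsv")
    manifest["steps"].append("data")

    arch = config.arch or ModelConfig(length=config.length,
                                      cell_types=tuple(config.cell_types))
    if arch.length != config.length:
        raise ConfigError("arch.length must match the run length")

    # ---- step 1: pretraining ------------------------------------------
    if config.do_pretrain and corpora:
        pre_cts = tuple(c for corpus in corpora for c in corpus.cell_types)
        pre_model = ExpressionModel(replace(arch, cell_types=pre_cts),
                                    seed=_derive(config.seed, 5))
        pre_cfg = replace(config.pretrain_cfg, alpha=0.0,
                          seed=_derive(config.seed, 6))
        pre_model = pretrain(pre_model, corpora, pre_cfg)
        base = transfer(pre_model, config.cell_types,
                        head=arch.head, seed=_derive(config.seed, 7))
    else:
        base = ExpressionModel(replace(arch, cell_types=tuple(config.cell_types)),
                               seed=_derive(config.seed, 7))
    manifest["steps"].append("pretrain")

    diagnostics = {c: dataclasses.asdict(diagnose_training_set(panel, c))
                   for c in config.cell_types}
    manifest["training_set_diagnostics"] = diagnostics

    sel_cfg = SelectionConfig(K=config.K, beta=config.beta, kmer_k=config.kmer_k)
    current_panel = panel
    for rnd in range(config.rounds):
        round_dir = out if config.rounds == 1 else out / f"round{rnd + 1}"
        round_dir.mkdir(exist_ok=True)
        round_info: dict = {"round": rnd + 1, "targets": {}}

        # ---- step 2: conservative fine-tuning -------------------------
        sweep = train_alpha_sweep(
            base, current_panel, alphas=config.alphas,
            train_cfg=replace(config.train, seed=_derive(config.seed, 10 + rnd)),
            inner_cfg=config.inner)
        manifest["steps"].append(f"finetune[{rnd + 1}]")

        # ---- ensemble --------------------------------------------------
        ens = build_ensemble(
            base, current_panel, size=config.ensemble_size,
            base_cfg=replace(config.train, alpha=0.0),
            split_seed=config.ensemble_split_seed,
            design_split_seed=config.train.split_seed,
            seed=_derive(config.seed, 20 + rnd))
        manifest["steps"].append(f"ensemble[{rnd + 1}]")

        new_measurements: list[SequencePanel] = []
        for target in config.targets:
            tdir = round_dir / target
            tdir.mkdir(exist_ok=True)
            # ---- step 3: design ---------------------------------------
            pool = design_pool(sweep, current_panel, target, config.inner,
                               master_seed=_derive(config.seed, 30 + rnd))
            pool.write(tdir / "pool.fasta", tdir / "pool.tsv")
            # ---- step 4: score, filter, select ------------------------
            scores = score_candidates(ens, pool, target)
            fpool, fscores = filter_candidates(
                scores, pool, ens, current_panel,
                expression_quantile=config.expression_quantile)
            write_scores(scores, ens, tdir / "scores.tsv",
                         kept_ids={c.id for c in fpool.candidates})
            if len(fpool) < config.K:
                raise DataError(
                    f"filtered pool for {target} has {len(fpool)} candidates, "
                    f"fewer than K={config.K}")
            result = greedy_select(fpool, fscores, sel_cfg)
            write_selection(result, tdir / "selected.fasta",
                            tdir / "selected.tsv")
            tres = TargetResult(
                target=target, pool_size=len(pool), filtered_size=len(fpool),
                fraction_improved=None, percent_gain_best=None,
                spearman_rho=None, mean_true_de_selected=None,
                mean_true_de_starts=None,
                mean_entropy=(result.diagnostics.mean_entropy
                              if result.diagnostics else None),
                mean_hamming=(result.diagnostics.mean_hamming
                              if result.diagnostics else None))
            # ---- step 5: oracle evaluation ----------------------------
            if config.mode == "oracle":
                eval_seed = _derive(config.seed, 40 + rnd * 10
                                    + list(config.targets).index(target))
                common = _spaced_common_set(current_panel, target,
                                            config.common_set_size)
                # re-id designs by candidate id: the same starting sequence
                # designed under two models must stay distinct in batch B
                chosen_seqs = [DnaSequence(c.id, c.sequence.bases)
                               for c in result.chosen]
                remeasured_ids = {s.id for s in current_panel.sequences
                                  if s.id in set(common.ids)}
                common_seqs = [s for s in current_panel.sequences
                               if s.id in remeasured_ids]
                batch_b_panel = measure_panel(chosen_seqs + common_seqs,
                                              grammar, seed=eval_seed)
                de_b = dict(zip(
                    [s.id for s in batch_b_panel.sequences],
                    batch_b_panel.measured_de(target)))
                de_a = dict(zip([s.id for s in current_panel.sequences],
                                current_panel.measured_de(target)))
                pairs = [(c.starting_id, c.id) for c in result.chosen]
                report = improvement_report(pairs, common, de_a, de_b)
                start_by_id = {s.id: s for s in current_panel.sequences}
                starts = [start_by_id[c.starting_id] for c in result.chosen]
                tres.fraction_improved = report.fraction_improved
                tres.spearman_rho = report.spearman_rho
                tres.percent_gain_best = percent_gain_best(
                    max(de_b[c.id] for c in result.chosen),
                    max(de_a.values()))
                tres.mean_true_de_selected = float(
                    true_de_batch(chosen_seqs, grammar, target).mean())
                tres.mean_true_de_starts = float(
                    true_de_batch(starts, grammar, target).mean())
                new_measurements.append(SequencePanel(
                    batch_b_panel.sequences[:len(chosen_seqs)],
                    batch_b_panel.expression[:len(chosen_seqs)],
                    batch_b_panel.cell_types))
            round_info["targets"][target] = dataclasses.asdict(tres)
            (tdir / "evaluation.json").write_text(
                json.dumps(dataclasses.asdict(tres), indent=1))
        manifest["rounds"].append(round_info)

        if rnd + 1 < config.rounds and new_measurements:
            extra_seqs = [s for p in new_measurements for s in p.sequences]
            extra_expr = np.concatenate([p.expression for p in new_measurements])
            current_panel = SequencePanel(
                current_panel.sequences + extra_seqs,
                np.concatenate([current_panel.expression, extra_expr]),
                current_panel.cell_types)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
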