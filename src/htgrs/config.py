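"""YAML experiment configuration.

One file with two blocks::

    synth:
      n_docs: 64
      label_noise_rate: 0.0
      seed: 7
    model:
      d_emb: 32
      N: 8
      L_g: 2
      L_rs: 2
      use_htg: true
      use_rs: true
      epochs: 40
      seed: 0

Unknown keys are rejected so typos fail loudly.  Trigger and
composition rules may be overridden under ``synth`` as lists of
mappings; by default the packaged study conditions apply.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .synthetic_corpus import CompositionRule, SynthConfig, TriggerRule, default_config
from .training_eval import ModelConfig

__all__ = ["load_config", "parse_config"]


def _synth_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    if "trigger_rules" in d:
        d["trigger_rules"] = tuple(TriggerRule(**r) for r in d["trigger_rules"])
    if "composition_rules" in d:
        d["composition_rules"] = tuple(CompositionRule(**r)
                                       for r in d["composition_rules"])
    for key in ("sentences_per_doc", "entities_per_doc", "mentions_per_entity",
                "relation_labels"):
        if key in d:
            d[key] = tuple(d[key])
    known = {f.name for f in fields(SynthConfig)}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown synth config keys: {sorted(bad)}")
    return default_config(**d)


def _model_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    if "labels" in d:
        d["labels"] = tuple(d["labels"])
    known = {f.name for f in fields(ModelConfig)}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown model config keys: {sorted(bad)}")
    return ModelConfig(**d)


def parse_config(text: str) -> tuple[SynthConfig, ModelConfig]:
    raw = yaml.safe_load(text) or {}
    synth = _synth_from_dict(raw.get("synth", {}))
    model = _model_from_dict(raw.get("model", {}))
    if "labels" not in raw.get("model", {}):
        model.labels = tuple(synth.relation_labels)
    return synth, model


def load_config(path: str) -> tuple[SynthConfig, ModelConfig]:
    with open(path) as fh:
        return parse_config(fh.read())
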