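"""Trace and specification file I/O.

Traces are tab-separated text with a required header (columns ``t``,
``nutrient`` and optionally ``switch_state``) plus a leading comment
line recording the alphabet, so a written trace round-trips losslessly.
Environment and model specifications are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .dbn import Hyperparameters, ModelSpec
from .environments import (
    MarkovEnvSpec,
    MetaEnvSpec,
    NutrientAlphabet,
    NutrientSequence,
)

__all__ = [
    "read_trace",
    "write_trace",
    "load_markov_spec",
    "load_meta_spec",
    "load_model_spec",
    "save_markov_spec",
    "save_meta_spec",
    "save_model_spec",
]

_ALPHABET_PREFIX = "# alphabet:"


def write_trace(seq: NutrientSequence, path: str | Path) -> None:
    """Write a nutrient trace as TSV (nutrient *names*, never indices)."""
    path = Path(path)
    has_states = seq.true_switch_states is not None
    lines = [_ALPHABET_PREFIX + " " + ",".join(seq.alphabet.labels)]
    header = ["t", "nutrient"] + (["switch_state"] if has_states else [])
    lines.append("\t".join(header))
    labels = seq.labels()
    for t, name in enumerate(labels):
        row = [str(t), name]
        if has_states:
            # switch states start at t=1; no state accompanies C_0
            row.append("" if t == 0 else str(int(seq.true_switch_states[t - 1])))
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path, alphabet: NutrientAlphabet | None = None) -> NutrientSequence:
    """Read a TSV trace back into a NutrientSequence.

    The alphabet is taken from the trace's comment line unless given
    explicitly; nutrient names outside the alphabet raise an error
    naming the offending line.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    lineno = 0
    while lineno < len(raw) and raw[lineno].startswith("#"):
        if raw[lineno].startswith(_ALPHABET_PREFIX) and alphabet is None:
            labels = [s.strip() for s in raw[lineno][len(_ALPHABET_PREFIX):].split(",")]
            alphabet = NutrientAlphabet(tuple(labels))
        lineno += 1
    body = [(i + 1, line) for i, line in enumerate(raw) if not raw[i].startswith("#")]
    body = [(n, line) for n, line in body if line.strip()]
    if not body:
        raise ValueError(f"{path}: empty trace")
    header_no, header = body[0]
    cols = header.split("\t")
    if cols[:2] != ["t", "nutrient"]:
        raise ValueError(f"{path}:{header_no}: expected header 't\\tnutrient[...]', got {header!r}")
    has_states = "switch_state" in cols
    obs: list[int] = []
    states: list[int] = []
    names_seen: list[str] = []
    for lineno, line in body[1:]:
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
        name = fields[1]
        if alphabet is None:
            names_seen.append(name)
            obs.append(-1)  # resolved after inferring the alphabet
        else:
            try:
                obs.append(alphabet.index(name))
            except KeyError:
                raise ValueError(
                    f"{path}:{lineno}: nutrient {name!r} not in alphabet {alphabet.labels}"
                ) from None
        if has_states and len(fields) > 2 and fields[2] != "":
            states.append(int(fields[2]))
    if not obs:
        raise ValueError(f"{path}: empty trace")
    if alphabet is None:
        ordered = tuple(dict.fromkeys(names_seen))
        alphabet = NutrientAlphabet(ordered)
        obs = [alphabet.index(n) for n in names_seen]
    return NutrientSequence(
        alphabet,
        np.array(obs, dtype=np.int64),
        true_switch_states=np.array(states, dtype=np.int64) if states else None,
    )


def _alphabet_from_yaml(doc: dict) -> NutrientAlphabet:
    return NutrientAlphabet(tuple(doc["alphabet"]))


def load_markov_spec(path: str | Path) -> MarkovEnvSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return MarkovEnvSpec(
        alphabet=_alphabet_from_yaml(doc),
        transition_matrix=np.asarray(doc["transition_matrix"], dtype=float),
        initial_state=int(doc.get("initial_state", 0)),
    )


def save_markov_spec(spec: MarkovEnvSpec, path: str | Path) -> None:
    doc = {
        "alphabet": list(spec.alphabet.labels),
        "transition_matrix": spec.transition_matrix.tolist(),
        "initial_state": int(spec.initial_state),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_meta_spec(path: str | Path) -> MetaEnvSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return MetaEnvSpec(
        alphabet=_alphabet_from_yaml(doc),
        switch_matrix=np.asarray(doc["switch_matrix"], dtype=float),
        state_matrices=np.asarray(doc["state_matrices"], dtype=float),
        initial_switch_state=int(doc.get("initial_switch_state", 0)),
        initial_nutrient=int(doc.get("initial_nutrient", 0)),
    )


def save_meta_spec(spec: MetaEnvSpec, path: str | Path) -> None:
    doc = {
        "alphabet": list(spec.alphabet.labels),
        "switch_matrix": spec.switch_matrix.tolist(),
        "state_matrices": spec.state_matrices.tolist(),
        "initial_switch_state": int(spec.initial_switch_state),
        "initial_nutrient": int(spec.initial_nutrient),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model_spec(path: str | Path) -> ModelSpec:
    doc = yaml.safe_load(Path(path).read_text())
    K, J = int(doc["K"]), int(doc["J"])
    hyper = Hyperparameters(
        alpha_s1=np.asarray(doc.get("alpha_s1", np.ones(K)), dtype=float),
        alpha_c0=np.asarray(doc.get("alpha_c0", np.ones(J)), dtype=float),
        alpha_c=np.asarray(doc.get("alpha_c", np.ones(J)), dtype=float),
        alpha_s_self=float(doc.get("alpha_s_self", 2.0)),
        alpha_s_other=float(doc.get("alpha_s_other", 1.0)),
    )
    return ModelSpec(K=K, J=J, hyper=hyper)


def save_model_spec(spec: ModelSpec, path: str | Path) -> None:
    h = spec.hyper
    doc = {
        "K": spec.K,
        "J": spec.J,
        "alpha_s1": h.alpha_s1.tolist(),
        "alpha_c0": h.alpha_c0.tolist(),
        "alpha_c": h.alpha_c.tolist(),
        "alpha_s_self": h.alpha_s_self,
        "alpha_s_other": h.alpha_s_other,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
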