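"""Strict structured configuration: dataclasses <-> nested dicts <-> YAML.

Unknown keys are rejected with the full section path; every default can
be dumped, and a dumped config re-parses to an equivalent object
(round-trip invariant).
"""
from __future__ import annotations

import dataclasses
import typing
from pathlib import Path
from typing import Any, Dict, Optional, Type, TypeVar, Union

import yaml

T = TypeVar("T")

__all__ = ["to_dict", "from_dict", "dump_yaml", "load_yaml"]


def to_dict(obj: Any) -> Dict[str, Any]:
    """Nested plain-dict view of a dataclass (tuples become lists)."""
    if not dataclasses.is_dataclass(obj):
        raise TypeError(f"expected a dataclass, got {type(obj)!r}")
    out: Dict[str, Any] = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            out[f.name] = to_dict(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def _strip_optional(tp):
    origin = typing.get_origin(tp)
    if origin is Union:
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return tp


def from_dict(cls: Type[T], data: Optional[Dict[str, Any]], path: str = "") -> T:
    """Build a dataclass from a nested dict, rejecting unknown keys.

    Missing keys take the dataclass defaults; list values are coerced to
    tuples where the field is tuple-typed.
    """
    data = dict(data or {})
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or cls.__name__
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {where}")
    kwargs: Dict[str, Any] = {}
    hints = typing.get_type_hints(cls)
    for name, f in fields.items():
        if name not in data:
            continue
        v = data[name]
        tp = _strip_optional(hints.get(name, f.type))
        if dataclasses.is_dataclass(tp) and isinstance(v, dict):
            v = from_dict(tp, v, path=f"{path}.{name}" if path else name)
        elif typing.get_origin(tp) is tuple and isinstance(v, list):
            v = tuple(v)
        kwargs[name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        where = path or cls.__name__
        raise ValueError(f"invalid config in section {where}: {exc}") from exc


def dump_yaml(obj: Any, path: Optional[Union[str, Path]] = None) -> str:
    text = yaml.safe_dump(to_dict(obj), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_yaml(cls: Type[T], source: Union[str, Path]) -> T:
    """Load a dataclass config from a YAML file path or YAML text."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("top-level config must be a mapping")
    return from_dict(cls, data)
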