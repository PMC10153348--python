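"""Tabular-to-text serialization: render a screen row as a fixed-template
sentence block and wrap it in the binary-classification prompt.

The default feature template reads

    The first drug is {drug1}. The second drug is {drug2}. The cell line is
    {cell_line}. Tissue is {tissue}. The first drug's sensitivity using
    relative inhibition is {sensitivity1}. The second drug's sensitivity
    using relative inhibition is {sensitivity2}.

and the full prompt is ``<instruction> <feature text> Synergy:`` with the
verbalizers "Positive" / "Not positive" standing for the two classes. Numeric
fields render from the input file's original strings (``raw_text``) when
available so serialization is byte-stable across read/write cycles.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from importlib import resources

from .schema_io import SynergyRecord

DEFAULT_INSTRUCTION = (
    "Decide in a single word if the synergy of the drug combination "
    "in the cell line is positive or not."
)
ANSWER_CUE = "Synergy:"
VERBALIZERS = ("Positive", "Not positive")

_TEMPLATE_FIELDS = (
    "drug1",
    "drug2",
    "cell_line",
    "tissue",
    "sensitivity1",
    "sensitivity2",
)


def load_template(name: str = "feature_default") -> str:
    """Load a named feature template shipped as package data."""
    path = resources.files("synergyshot.templates").joinpath(f"{name}.txt")
    return path.read_text(encoding="utf-8").rstrip("\n")

def _render_number(value: float) -> str:
    # shortest round-trip decimal; 0.568 stays "0.568"
    return repr(value)


def record_fields(record: SynergyRecord) -> dict[str, str]:
    raw = record.raw_text or {}
    return {
        "drug1": raw.get("drug1", record.drug1_name),
        "drug2": raw.get("drug2", record.drug2_name),
        "cell_line": raw.get("cell_line", record.cell_line_name),
        "tissue": raw.get("tissue", record.tissue_name),
        "sensitivity1": raw.get("sensitivity1", _render_number(record.sensitivity1)),
        "sensitivity2": raw.get("sensitivity2", _render_number(record.sensitivity2)),
    }


def serialize_record(record: SynergyRecord, template: str | None = None) -> str:
    """Render one record through a ``{field}``-placeholder template."""
    record.validate()
    tmpl = template if template is not None else load_template()
    fields = record_fields(record)
    for _, placeholder, _, _ in string.Formatter().parse(tmpl):
        if placeholder is not None and placeholder not in fields:
            raise KeyError(
                f"template placeholder {{{placeholder}}} does not name a record field; "
                f"known fields: {sorted(fields)}"
            )
    return tmpl.format(**fields)


@dataclass
class PromptText:
    feature_text: str
    full_prompt: str
    verbalizers: tuple[str, str] = VERBALIZERS


def build_prompt(
    feature_text: str,
    instruction: str = DEFAULT_INSTRUCTION,
    answer_cue: str = ANSWER_CUE,
    verbalizers: tuple[str, str] = VERBALIZERS,
) -> PromptText:
    """Join instruction, serialized features and answer cue into one prompt.

    The feature block already ends with a period, so the parts are joined
    with single spaces and no extra punctuation; the result never contains
    doubled periods when the feature block is a well-formed sentence block.
    """
    if not feature_text:
        raise ValueError("feature_text must be non-empty")
    if not instruction and not answer_cue:
        raise ValueError("instruction and answer_cue cannot both be empty")
    parts = [p for p in (instruction, feature_text, answer_cue) if p]
    full = " ".join(parts)
    return PromptText(feature_text=feature_text, full_prompt=full, verbalizers=verbalizers)


def prompt_for_record(
    record: SynergyRecord,
    template: str | None = None,
    instruction: str = DEFAULT_INSTRUCTION,
) -> PromptText:
    return build_prompt(serialize_record(record, template), instruction)


def template_regex(template: str | None = None) -> re.Pattern:
    """Regex matching any rendering of a template, one group per placeholder."""
    tmpl = template if template is not None else load_template()
    out = []
    for literal, placeholder, _, _ in string.Formatter().parse(tmpl):
        out.append(re.escape(literal))
        if placeholder is not None:
            out.append(f"(?P<{placeholder}>.+?)")
    return re.compile("^" + "".join(out) + "$")
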