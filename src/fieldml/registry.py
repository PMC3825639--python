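"""Registry of external-evaluator implementations.

External evaluators carry semantics by convention only; executable meaning
is supplied here, keyed by the evaluator's fully qualified name.  The
standard library registers its interpolators and shape predicates on load;
applications may register their own externals the same way.
"""
from __future__ import annotations

from typing import Callable, Dict

# name -> callable(external_evaluator, argument_values, config) -> Value
EXTERNAL_IMPLEMENTATIONS: Dict[str, Callable] = {}


def register(name: str, implementation: Callable) -> None:
    EXTERNAL_IMPLEMENTATIONS[name] = implementation


def implementation_for(name: str):
    return EXTERNAL_IMPLEMENTATIONS.get(name)
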