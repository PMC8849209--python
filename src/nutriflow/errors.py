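"""Exception hierarchy.

All package errors derive from :class:`NutriflowError` so callers (and the
CLI) can distinguish validation failures from runtime failures by type.
"""

from __future__ import annotations


class NutriflowError(Exception):
    """Base class for all package errors."""


class BundleValidationError(NutriflowError):
    """A dataset bundle violates one or more schema invariants.

    Parameters
    ----------
    problems:
        Human-readable descriptions, one per violated invariant, each naming
        the offending table/identifier.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n  - "
            + "\n  - ".join(self.problems)
        )


class ParseError(NutriflowError):
    """A CSV file could not be parsed; names the file."""


class TaxonomyError(NutriflowError):
    """A commodity or group reference does not resolve against the taxonomy."""


class UnitError(NutriflowError):
    """A quantity's declared unit disagrees with the unit registry."""


class BalanceError(NutriflowError):
    """A commodity balance is infeasible (e.g. nonzero global net trade
    in strict mode, or negative net supply beyond tolerance)."""


class GraphError(NutriflowError):
    """The processing parent->child graph is cyclic or otherwise invalid."""


class DomainError(NutriflowError):
    """A scalar argument is outside its mathematical domain."""


class ScenarioError(NutriflowError):
    """A scenario specification is inconsistent (e.g. a removed group is
    also scaled, or the donor is among the removed groups)."""
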