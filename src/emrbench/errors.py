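"""Exception hierarchy.

All failures raised by this package derive from :class:`EmrBenchError`, so
callers (and the command-line wrapper) can distinguish data problems from
programming errors with a single ``except`` clause.
"""


class EmrBenchError(Exception):
    """Base class for all errors raised by emrbench."""


class ParseError(EmrBenchError):
    """The input document is not well-formed XML (or YAML)."""


class SchemaValidationError(EmrBenchError):
    """A well-formed document violates the shipped schema."""


class IntegrityError(EmrBenchError):
    """A structural invariant is violated (duplicate ids, bad references,
    incomplete coverage, mismatched family ids)."""


class ResolutionError(EmrBenchError):
    """One or more scenario references cannot be resolved."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            "unresolvable scenario reference(s): " + ", ".join(self.missing_ids)
        )


class DomainError(EmrBenchError, ValueError):
    """A value lies outside its admissible domain (e.g. an unknown rating
    label)."""


class MissingDataError(EmrBenchError):
    """A rating required under the strict missing-data policy is absent."""


class UndefinedScoreError(EmrBenchError):
    """A score's denominator is empty (no rated item/rater pairs)."""


class StrategyCompileError(EmrBenchError):
    """A search-strategy definition cannot be compiled."""


class ConfigError(EmrBenchError):
    """A generator or panel configuration violates its invariants."""
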