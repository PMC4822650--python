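"""Exception hierarchy.

All phenowalk errors derive from :class:`PhenoWalkError` so callers can
catch the package's failures with a single except clause; subclasses keep
the distinction between bad user configuration, malformed input files and
numerical failures.
"""


class PhenoWalkError(Exception):
    """Base class for all phenowalk errors."""


class ConfigurationError(PhenoWalkError, ValueError):
    """A parameter or input combination that can never be valid."""


class SchemaError(PhenoWalkError, ValueError):
    """An input table or file is missing required structure (columns, stanzas)."""


class StructuralError(PhenoWalkError, ValueError):
    """A graph violates a structural invariant (e.g. a cycle in an ontology)."""


class ConvergenceError(PhenoWalkError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""
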