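"""Exception hierarchy.

Everything raised on purpose derives from :class:`HeteroPathError` so callers
can catch the package's own failures without masking programming errors.
"""


class HeteroPathError(Exception):
    """Base class for all errors raised by heteropath."""


class EdgeListParseError(HeteroPathError, ValueError):
    """A TSV edge-list line could not be parsed; the message names the line."""


class DuplicateEdgeError(HeteroPathError, ValueError):
    """The same ordered (source, target) pair appeared twice in an edge set."""


class ConfigError(HeteroPathError, ValueError):
    """Invalid configuration (cutoffs, type-pair collisions, bad parameters)."""


class MissingRelationError(HeteroPathError, KeyError):
    """A metapath step requires a relation the network does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return super(Exception, self).__str__() or repr(self.args)


class NodeLookupError(HeteroPathError, KeyError):
    """A node identifier is not indexed under the requested node type."""

    def __str__(self) -> str:
        return super(Exception, self).__str__() or repr(self.args)


class SchemaError(HeteroPathError, ValueError):
    """Feature columns do not match what a fitted classifier was trained on."""


class TrainingError(HeteroPathError, ValueError):
    """Training input is unusable (e.g. a single label class)."""


class SamplingError(HeteroPathError, ValueError):
    """Requested positive/negative sample counts are infeasible."""


class EvaluationError(HeteroPathError, ValueError):
    """Evaluation input is unusable (length mismatch, single-class labels)."""


class ProtocolError(HeteroPathError, ValueError):
    """An evaluation protocol constraint is violated (e.g. train/test overlap)."""
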