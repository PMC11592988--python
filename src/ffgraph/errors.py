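"""Exception hierarchy for graph construction, model semantics and inference."""


class FFGraphError(Exception):
    """Base class for all ffgraph errors."""


# -- graph construction -------------------------------------------------------

class DuplicateName(FFGraphError):
    """A variable with the same (name, index, path) already exists."""


class MissingValue(FFGraphError):
    """A constant or data variable was declared without a value."""


class UnknownVariable(FFGraphError):
    """A factor references a variable id absent from the graph."""


class EmptyInterfaces(FFGraphError):
    """A factor was declared with an empty interface map."""


class UnknownFactor(FFGraphError):
    """A factor id absent from the graph was referenced."""


# -- model language -----------------------------------------------------------

class DuplicateLabel(FFGraphError):
    """A node type label is already registered."""


class EvaluatorMissing(FFGraphError):
    """A deterministic node type was registered without an evaluator."""


class AmbiguousAlias(FFGraphError):
    """Two or more alias rules match the supplied keyword set."""


class UnknownKeywordSet(FFGraphError):
    """No alias rule matches the supplied keyword set."""


class UnknownLabel(FFGraphError):
    """A statement uses a label that is not registered."""


class UnresolvableReference(FFGraphError):
    """A right-hand-side variable reference cannot be resolved in scope."""


class DuplicateInterface(FFGraphError):
    """A model definition declares the same interface name twice."""


class NoMissingInterface(FFGraphError):
    """A submodel invocation supplied all interfaces but also a left-hand side."""


class MultipleMissingInterfaces(FFGraphError):
    """A submodel invocation left more than one interface unbound."""


class UnknownInterface(FFGraphError):
    """A submodel invocation supplied a keyword that is not an interface."""


# -- plugins / constraints ----------------------------------------------------

class UnknownTarget(FFGraphError):
    """A plugin payload targets a node id absent from the graph."""


class ConflictingConstraints(FFGraphError):
    """Two factorization constraints over the same variables disagree."""


class MalformedPartition(FFGraphError):
    """A factorization constraint's partition is not a partition of its variables."""


class UnknownConstraintVariable(FFGraphError):
    """A constraint names a variable that does not resolve in its scope."""


class UnknownFamily(FFGraphError):
    """A functional-form constraint names an unregistered distribution family."""


# -- inference ----------------------------------------------------------------

class StateSpaceTooLarge(FFGraphError):
    """The joint discrete state space exceeds the enumeration cap."""


class SupportMismatch(FFGraphError):
    """A belief places mass where the reference distribution has none."""


class NotSupported(FFGraphError):
    """The model is outside the engine's supported conjugate/discrete class."""


# -- serialization ------------------------------------------------------------

class SchemaViolation(FFGraphError):
    """A graph document does not match the expected schema."""


class VersionMismatch(FFGraphError):
    """A graph document declares an unsupported format version."""
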