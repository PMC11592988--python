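"""Plugin payloads: backend-specific information attached to graph elements.

Payloads are namespaced per plugin; one plugin cannot read (or clobber)
another's records.  A target is a factor id, a variable id, or the graph
itself (``GRAPH_TARGET``).
"""

from __future__ import annotations

import logging
from typing import Any, Optional

from .errors import UnknownTarget
from .graph import FactorGraph

logger = logging.getLogger(__name__)

GRAPH_TARGET = "__graph__"


def attach_payload(graph: FactorGraph, plugin_name: str, target: str,
                   payload: Any) -> None:
    """Attach a serializable payload to a node (or the whole graph).

    Re-attaching to the same target overwrites the previous payload and logs
    a warning.
    """
    if target != GRAPH_TARGET and target not in graph.variables \
            and target not in graph.factors:
        raise UnknownTarget(f"no node with id {target!r} in graph")
    store = graph.plugins.setdefault(plugin_name, {})
    if target in store:
        logger.warning("plugin %r overwrites payload on %r", plugin_name, target)
    store[target] = payload


def get_payload(graph: FactorGraph, plugin_name: str,
                target: str) -> Optional[Any]:
    return graph.plugins.get(plugin_name, {}).get(target)


def payloads(graph: FactorGraph, plugin_name: str) -> dict[str, Any]:
    """All payloads attached by one plugin, keyed by target id."""
    return dict(graph.plugins.get(plugin_name, {}))
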