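"""Label deletion breakpoints with the repeat or SVA substructure they hit.

Breakpoint typing follows the scheme of the published per-locus table: a
breakpoint inside an SVA element is labelled with its substructure code
(1 Alu-like, 2 VNTR, 3 SINE-R, 4 poly-A, 5 hexamer, 6 SVA2-specific), a
breakpoint inside any other annotated repeat with that repeat's name, and
anything else as unique sequence.  A breakpoint exactly on a segment
boundary belongs to the downstream segment (half-open convention).
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import (
    BreakpointAnnotation,
    BreakpointKind,
    DeletionCall,
    EventType,
    RepeatFeature,
    SVAElement,
    SvaSegment,
)

logger = logging.getLogger(__name__)


def map_breakpoint_to_sva_segment(pos: int, element: SVAElement) -> Optional[SvaSegment]:
    """Substructure code of the segment containing ``pos``, or None if outside."""
    if not element.segments:
        raise ValueError("element has no substructure annotation")
    return element.segment_at(pos)


def annotate_breakpoint(
    pos: int,
    seq_id: str,
    annotations: Sequence[RepeatFeature],
    sva_elements: Sequence[SVAElement],
) -> BreakpointAnnotation:
    """Annotate one breakpoint position; total over {SVA_SEGMENT, REPEAT, UNIQUE}.

    SVA elements (with substructure) take precedence; among plain repeat
    features covering the position, the smallest wins (logged).
    """
    for el in sva_elements:
        if el.interval.contains_point(pos, seq_id) and el.segments:
            code = el.segment_at(pos)
            if code is not None:
                return BreakpointAnnotation(BreakpointKind.SVA_SEGMENT,
                                            sva_segment_code=code)
    covering = [f for f in annotations if f.interval.contains_point(pos, seq_id)]
    if covering:
        covering.sort(key=lambda f: (f.interval.length(), f.repeat_name))
        if len(covering) > 1:
            logger.info("breakpoint %s:%d covered by %d features; using smallest (%s)",
                        seq_id, pos, len(covering), covering[0].repeat_name)
        return BreakpointAnnotation(BreakpointKind.REPEAT,
                                    repeat_name=covering[0].repeat_name)
    return BreakpointAnnotation(BreakpointKind.UNIQUE)


def annotate_calls(
    calls: Sequence[DeletionCall],
    ancestral_annotations: Sequence[RepeatFeature],
    sva_elements: Sequence[SVAElement] = (),
) -> List[DeletionCall]:
    """Attach left/right breakpoint annotations (ancestral coordinates) to SRADs."""
    out = []
    for call in calls:
        if call.event_type != EventType.SRAD:
            out.append(call)
            continue
        iv = call.ancestral_deleted
        out.append(dataclasses.replace(
            call,
            left_breakpoint_annotation=annotate_breakpoint(
                iv.start, iv.seq_id, ancestral_annotations, sva_elements),
            right_breakpoint_annotation=annotate_breakpoint(
                iv.end, iv.seq_id, ancestral_annotations, sva_elements),
        ))
    return out


def tabulate_breakpoint_positions(calls: Sequence[DeletionCall]) -> Dict[SvaSegment, int]:
    """Count SVA-substructure breakpoints per segment code over SRAD calls.

    Each SVA-annotated breakpoint contributes once; non-SVA breakpoints do
    not contribute.
    """
    pairs = []
    for call in calls:
        if call.event_type != EventType.SRAD:
            continue
        pairs.append((
            _code_of(call.left_breakpoint_annotation),
            _code_of(call.right_breakpoint_annotation),
        ))
    return tabulate_segment_codes(pairs)


def tabulate_segment_codes(
    code_pairs: Iterable[Tuple[Optional[SvaSegment], Optional[SvaSegment]]],
) -> Dict[SvaSegment, int]:
    counts: Counter = Counter()
    for left, right in code_pairs:
        for code in (left, right):
            if code is not None:
                counts[SvaSegment(code)] += 1
    return {code: counts.get(code, 0) for code in SvaSegment}


def _code_of(ann: Optional[BreakpointAnnotation]) -> Optional[SvaSegment]:
    if ann is not None and ann.kind == BreakpointKind.SVA_SEGMENT:
        return ann.sva_segment_code
    return None
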