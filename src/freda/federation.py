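"""Message transcript and information-flow audit for the simulated parties.

All parties run in one process; every cross-party payload is logged as an
append-only transcript entry carrying a content digest.  The audit replays
the transcript against the set of *private* payload digests (raw data
matrices, individual feature columns, label vectors, mask seeds) and fails
if any private payload ever crossed a trust boundary, or if mask keying
material was routed to the aggregator.  This operationalizes the semi-honest
trust model as a checkable artifact rather than a proof.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["Message", "ProtocolTranscript", "AuditReport", "audit_transcript", "payload_digest"]

AGGREGATOR = "aggregator"
TARGET = "target"

# Payload tags that legitimately carry mask keying material between the
# data-holding parties (never to the aggregator).
MASK_MATERIAL_TAGS = frozenset({"mask-seed", "mask-bundle", "pairwise-seed"})


def payload_digest(payload) -> str:
    """Stable content digest of a message payload."""
    h = hashlib.sha256()
    if isinstance(payload, np.ndarray):
        arr = np.ascontiguousarray(payload)
        h.update(str(arr.dtype).encode())
        h.update(str(arr.shape).encode())
        h.update(arr.tobytes())
    elif isinstance(payload, (bytes, bytearray)):
        h.update(bytes(payload))
    else:
        h.update(json.dumps(payload, sort_keys=True, default=str).encode())
    return h.hexdigest()


@dataclass(frozen=True)
class Message:
    round_id: int
    sender: str
    receiver: str
    tag: str
    shape: tuple
    digest: str


class ProtocolTranscript:
    """Append-only ordered log of cross-party messages."""

    def __init__(self) -> None:
        self._messages: list[Message] = []

    def record(self, round_id: int, sender: str, receiver: str, tag: str, payload) -> None:
        shape = tuple(payload.shape) if isinstance(payload, np.ndarray) else ()
        self._messages.append(
            Message(int(round_id), sender, receiver, tag, shape, payload_digest(payload))
        )

    @property
    def messages(self) -> tuple[Message, ...]:
        return tuple(self._messages)

    def __len__(self) -> int:
        return len(self._messages)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self._messages:
                fh.write(
                    json.dumps(
                        {
                            "round": m.round_id,
                            "sender": m.sender,
                            "receiver": m.receiver,
                            "tag": m.tag,
                            "shape": list(m.shape),
                            "digest": m.digest,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "ProtocolTranscript":
        t = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            t._messages.append(
                Message(
                    d["round"], d["sender"], d["receiver"], d["tag"], tuple(d["shape"]), d["digest"]
                )
            )
        return t


@dataclass
class AuditReport:
    passed: bool
    n_messages: int
    violations: list[str] = field(default_factory=list)
    permitted_masked_payloads: int = 0


def audit_transcript(
    transcript: ProtocolTranscript, private_digests: Iterable[str]
) -> AuditReport:
    """PASS iff no private payload digest appears in any cross-party message
    and no mask keying material was delivered to the aggregator."""
    private = set(private_digests)
    violations = []
    masked_ok = 0
    for i, m in enumerate(transcript.messages):
        if m.sender == m.receiver:
            continue
        if m.tag in MASK_MATERIAL_TAGS:
            # keying material may move between the data-holding parties;
            # only the aggregator must never receive it (checked below)
            if m.receiver == AGGREGATOR:
                violations.append(
                    f"message {i}: mask material (tag={m.tag!r}) routed to the aggregator"
                )
            continue
        if m.digest in private:
            violations.append(
                f"message {i} ({m.sender}->{m.receiver}, tag={m.tag!r}): "
                "payload digest matches a private payload"
            )
        if m.tag in ("encoded-matrix", "secure-sum-share", "masked-mean-block"):
            masked_ok += 1
    return AuditReport(
        passed=not violations,
        n_messages=len(transcript),
        violations=violations,
        permitted_masked_payloads=masked_ok,
    )
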