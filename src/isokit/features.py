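"""User-provided functional features: loading, validation and projection.

Positional features (protein domains, signal peptides, nuclear localization
signals) arrive in amino-acid coordinates (1-based inclusive, the convention
of domain databases) or transcript nucleotide coordinates (0-based
half-open).  Non-positional attributes are binary, categorical or continuous
values attached to a transcript.  Both kinds come from a single TSV and can
be merged back into a GTF as extra records / transcript attributes so a
single augmented annotation drives the figures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import IsokitError, SchemaError, ValidationError
from .genemodels import FeatureRecord, GeneModel, Transcript, project_interval

__all__ = [
    "PositionalFeature",
    "NonPositionalFeature",
    "load_features",
    "write_features",
    "project_protein_feature",
    "merge_into_annotation",
    "extract_features",
]

POSITIONAL_KINDS = {"domain", "signal_peptide", "nls", "custom"}
SPACES = {"protein_aa", "transcript_nt"}
DTYPES = {"binary", "categorical", "continuous"}


@dataclass(frozen=True)
class PositionalFeature:
    transcript_id: str
    kind: str  # domain | signal_peptide | nls | custom
    space: str  # protein_aa (1-based inclusive) | transcript_nt (0-based half-open)
    start: int
    end: int
    label: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.kind not in POSITIONAL_KINDS:
            raise ValidationError(f"unknown positional feature kind {self.kind!r}")
        if self.space not in SPACES:
            raise ValidationError(f"unknown coordinate space {self.space!r}")
        if self.space == "protein_aa" and not (1 <= self.start <= self.end):
            raise ValidationError(f"{self.label}: need 1 <= start <= end in aa space")
        if self.space == "transcript_nt" and not (0 <= self.start < self.end):
            raise ValidationError(f"{self.label}: need 0 <= start < end in nt space")


@dataclass(frozen=True)
class NonPositionalFeature:
    transcript_id: str
    name: str
    dtype: str  # binary | categorical | continuous
    value: bool | str | float

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValidationError(f"unknown dtype {self.dtype!r}")
        ok = {"binary": bool, "categorical": str, "continuous": float}[self.dtype]
        if not isinstance(self.value, ok):
            raise ValidationError(
                f"{self.name}: value {self.value!r} does not match dtype {self.dtype}"
            )


_COLUMNS = ["row_type", "transcript_id", "kind_or_name", "space_or_dtype",
            "start", "end", "label_or_value"]


def _parse_np_value(dtype: str, raw: str, rowno: int) -> bool | str | float:
    if dtype == "binary":
        if str(raw).lower() in ("true", "1", "yes"):
            return True
        if str(raw).lower() in ("false", "0", "no"):
            return False
        raise SchemaError(f"row {rowno}: binary value {raw!r} is not boolean")
    if dtype == "continuous":
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise SchemaError(
                f"row {rowno}: continuous value {raw!r} is not numeric"
            ) from None
    return str(raw)


def load_features(path, known_transcripts: set[str] | None = None):
    """Load a mixed feature TSV.

    Returns (positional, non_positional, warnings); rows referring to
    transcripts absent from ``known_transcripts`` are reported as warnings
    rather than failing the load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"feature table is missing column {col!r}")
    positional: list[PositionalFeature] = []
    non_positional: list[NonPositionalFeature] = []
    warnings: list[str] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based with header
        tid = str(row["transcript_id"])
        if known_transcripts is not None and tid not in known_transcripts:
            warnings.append(f"row {rowno}: unknown transcript {tid}")
            continue
        if row["row_type"] == "positional":
            try:
                positional.append(PositionalFeature(
                    tid, str(row["kind_or_name"]), str(row["space_or_dtype"]),
                    int(row["start"]), int(row["end"]), str(row["label_or_value"]),
                ))
            except (ValueError, ValidationError) as exc:
                raise SchemaError(f"row {rowno}: {exc}") from None
        elif row["row_type"] == "non_positional":
            dtype = str(row["space_or_dtype"])
            if dtype not in DTYPES:
                raise SchemaError(f"row {rowno}: unknown dtype {dtype!r}")
            value = _parse_np_value(dtype, row["label_or_value"], rowno)
            non_positional.append(NonPositionalFeature(
                tid, str(row["kind_or_name"]), dtype, value))
        else:
            raise SchemaError(f"row {rowno}: unknown row_type {row['row_type']!r}")
    return positional, non_positional, warnings


def write_features(positional, non_positional, path) -> None:
    rows = []
    for f in positional:
        rows.append(["positional", f.transcript_id, f.kind, f.space,
                     f.start, f.end, f.label])
    for f in non_positional:
        rows.append(["non_positional", f.transcript_id, f.name, f.dtype,
                     0, 0, f.value])
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_protein_feature(f: PositionalFeature, tx: Transcript):
    """Genomic intervals of a protein-space feature on its transcript.

    Amino acids a..b (1-based inclusive) map to CDS-relative nucleotides
    [3(a-1), 3b), then through the CDS chain to the genome, splitting at exon
    junctions.  Features extending past an incomplete CDS are clipped and the
    returned feature copy carries ``clipped=True``.
    """
    if f.space != "protein_aa":
        raise IsokitError("project_protein_feature expects protein_aa space")
    if not tx.cds:
        raise IsokitError(
            f"{tx.transcript_id} has no CDS; protein feature {f.label} cannot be placed"
        )
    cds_start, cds_end = tx.cds_transcript_range()
    nt_start = cds_start + 3 * (f.start - 1)
    nt_end = cds_start + 3 * f.end
    clipped = False
    if nt_end > cds_end:
        nt_end = cds_end
        clipped = True
    if nt_start >= nt_end:
        raise IsokitError(
            f"{f.label}: aa range {f.start}-{f.end} is beyond the CDS of "
            f"{tx.transcript_id}"
        )
    return project_interval(tx, nt_start, nt_end), replace(f, clipped=clipped)


def project_positional_feature(f: PositionalFeature, tx: Transcript):
    """Project either coordinate space to genomic intervals."""
    if f.space == "protein_aa":
        return project_protein_feature(f, tx)
    if f.end > tx.spliced_length:
        raise IsokitError(f"{f.label}: beyond spliced length of {tx.transcript_id}")
    return project_interval(tx, f.start, f.end), f


# ---------------------------------------------------------------------------
# merging into the annotation
# ---------------------------------------------------------------------------

def merge_into_annotation(models: list[GeneModel], positional,
                          non_positional) -> list[GeneModel]:
    """Attach features to gene models so write_gtf emits them.

    Positional features become extra GTF records (feature type = kind) with
    ``feature_label``/``feature_space``/coordinate attributes; non-positional
    features become transcript attributes ``np_<name>`` with a dtype tag.
    A parse of the written GTF recovers every feature via
    :func:`extract_features`.
    """
    by_tx_pos: dict[str, list[PositionalFeature]] = {}
    for f in positional:
        by_tx_pos.setdefault(f.transcript_id, []).append(f)
    by_tx_np: dict[str, list[NonPositionalFeature]] = {}
    for f in non_positional:
        by_tx_np.setdefault(f.transcript_id, []).append(f)

    out = []
    for gm in models:
        new_txs = []
        for tx in gm.transcripts:
            extra = list(tx.extra_records)
            attrs = dict(tx.attributes)
            for f in by_tx_pos.get(tx.transcript_id, []):
                segments, projected = project_positional_feature(f, tx)
                for iv in segments:
                    extra.append(FeatureRecord(
                        feature_type=f.kind,
                        interval=iv,
                        attributes=(
                            ("feature_label", f.label),
                            ("feature_source", "user"),
                            ("feature_space", f.space),
                            ("feature_start", str(f.start)),
                            ("feature_end", str(f.end)),
                            ("feature_clipped", str(projected.clipped)),
                        ),
                    ))
            for f in by_tx_np.get(tx.transcript_id, []):
                attrs[f"np_{f.name}"] = f"{f.dtype}:{f.value}"
            new_txs.append(replace(tx, extra_records=extra, attributes=attrs))
        out.append(GeneModel(gm.gene_id, new_txs))
    return out


def extract_features(models: list[GeneModel]):
    """Recover positional/non-positional features from an augmented model."""
    positional: list[PositionalFeature] = []
    non_positional: list[NonPositionalFeature] = []
    for gm in models:
        for tx in gm.transcripts:
            seen: set[tuple] = set()
            for rec in tx.extra_records:
                if rec.feature_type not in POSITIONAL_KINDS:
                    continue
                a = dict(rec.attributes)
                key = (a["feature_label"], a["feature_space"],
                       a["feature_start"], a["feature_end"])
                if key in seen:
                    continue  # one logical feature may span several segments
                seen.add(key)
                positional.append(PositionalFeature(
                    tx.transcript_id, rec.feature_type, a["feature_space"],
                    int(a["feature_start"]), int(a["feature_end"]),
                    a["feature_label"],
                    clipped=a.get("feature_clipped", "False") == "True",
                ))
            for k, v in tx.attributes.items():
                if not k.startswith("np_"):
                    continue
                dtype, _, raw = v.partition(":")
                value = _parse_np_value(dtype, raw, 0)
                non_positional.append(NonPositionalFeature(
                    tx.transcript_id, k[3:], dtype, value))
    return positional, non_positional
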