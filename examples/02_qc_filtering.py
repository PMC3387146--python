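"""Demultiplex and quality-filter a small multiplexed read pool.

Uses the built-in designed-defect read set: ten reads of which six each
violate exactly one curation rule (length, mean quality, ambiguous base,
barcode, reverse-primer mismatches) and four are clean.
"""

from ampliclass import QcPolicy, run_qc
from ampliclass.synthetic import designed_defect_fixture

reads, barcode_map, expected = designed_defect_fixture()
policy = QcPolicy(barcode_map=barcode_map)  # defaults: 200-600 nt, mean Q>=25,
                                            # no ambiguous bases, exact barcode,
                                            # <=4 reverse-primer mismatches
processed, fate_log, summary = run_qc(reads, policy)

print(fate_log.to_string(index=False))
print(f"\npassed {summary['passed']}/{summary['total']}; rejections:",
      {k: v for k, v in summary["rejected"].items() if v})
# Each rejection reason matches the defect designed into that read; passing
# reads come out demultiplexed with barcode and primers trimmed.
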