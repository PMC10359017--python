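"""Is a norm evolutionarily stable, and for which benefit-to-cost ratios?

Runs the finite-error CESS check for Stern Judging (L6) and Forgiver (S16)
against all 15 deviating deterministic action rules, and compares the
resulting b/c interval with the closed-form rare-error classification.
"""

from recinorm import catalog_lookup, cess_check, classify_cess

for name in ("L6", "S16"):
    norm = catalog_lookup(name)
    numerical = cess_check(norm)              # mu = 1e-3, p_th = 0.98
    analytic = classify_cess(norm)            # rare-error limit, exact
    print(f"{name}: CESS = {numerical.is_cess}")
    print(f"  numerical interval  b/c in ({numerical.bc_lower:.4f}, "
          f"{numerical.bc_upper})")
    print(f"  analytic  interval  b/c in ({analytic.bc_lower:g}, "
          f"{analytic.bc_upper})  branch {analytic.branch}")

print("-> L6 is stable whenever cooperation pays at all (b/c > 1); the "
      "lenient S16 needs twice the benefit (b/c > 2).")
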