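"""Data views: named selections of named-graph classes.

A first-level view covers one class (the parthood view); a combined view
covers several (general-measurements = every measurement class); a filtered
view additionally constrains units (lengths-and-distances keeps only
metre-based measurements, so the worked example's milliliter volume drops
out)."""

from anatomykg import paper_example
from anatomykg.views import default_views, resolve_view

store, doc = paper_example()
registry = default_views(store)

for name in ("parthood-view", "anatomical-surface-texture-view",
             "general-measurements", "lengths-and-distances"):
    stmts = resolve_view(store, doc, registry.get(name))
    print(f"{name:35s} -> {len(stmts):2d} statements")

print("\nlengths-and-distances is empty: the only measurement is a volume in")
print("milliliter, which the metre-based unit filter excludes.")
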