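# Literature-curated differentially methylated genes in primary biliary
# cholangitis with suggestive X-chromosome association signals.
PIN4
NHS
IL1RAPL2
SHROOM2
ATP6AP2
PQBP1
MAGEB2
NSDHL
PIM2
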