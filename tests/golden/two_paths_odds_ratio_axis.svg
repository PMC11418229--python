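<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="626.00" height="212.00" viewBox="0 0 626.00 212.00">
<rect x="0" y="0" width="626.00" height="212.00" fill="#ffffff"/>
<text x="14.00" y="26.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" font-weight="bold">dose response</text>
<text x="369.00" y="54.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">control</text>
<text x="537.00" y="54.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">treated</text>
<text x="14.00" y="81.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">root process</text>
<line x1="294.00" y1="77.00" x2="612.00" y2="77.00" stroke="#eeeeee" stroke-width="1"/>
<text x="28.00" y="103.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">branch B</text>
<line x1="294.00" y1="99.00" x2="612.00" y2="99.00" stroke="#eeeeee" stroke-width="1"/>
<text x="42.00" y="125.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">join D</text>
<line x1="294.00" y1="121.00" x2="612.00" y2="121.00" stroke="#eeeeee" stroke-width="1"/>
<rect x="298.50" y="114.00" width="3.00" height="14.00" fill="#9e9e9e" class="fold-bar"/>
<polygon points="300.60,116.50 295.60,125.50 305.60,125.50" fill="#f7b6d2" class="odds-ratio-triangle"/>
<rect x="496.50" y="114.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="612.00,116.50 607.00,125.50 617.00,125.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<path d="M 609.50 113.50 L 612.00 110.50 L 614.50 113.50" stroke="#333333" stroke-width="1" fill="none" class="overflow-marker"/>
<text x="28.00" y="147.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">branch C</text>
<line x1="294.00" y1="143.00" x2="612.00" y2="143.00" stroke="#eeeeee" stroke-width="1"/>
<text x="42.00" y="169.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">join D</text>
<line x1="294.00" y1="165.00" x2="612.00" y2="165.00" stroke="#eeeeee" stroke-width="1"/>
<rect x="298.50" y="158.00" width="3.00" height="14.00" fill="#9e9e9e" class="fold-bar"/>
<polygon points="300.60,160.50 295.60,169.50 305.60,169.50" fill="#f7b6d2" class="odds-ratio-triangle"/>
<rect x="496.50" y="158.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="612.00,160.50 607.00,169.50 617.00,169.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<path d="M 609.50 157.50 L 612.00 154.50 L 614.50 157.50" stroke="#333333" stroke-width="1" fill="none" class="overflow-marker"/>
<line x1="294.00" y1="182.00" x2="444.00" y2="182.00" stroke="#333333" stroke-width="1"/>
<line x1="294.00" y1="182.00" x2="294.00" y2="186.00" stroke="#333333" stroke-width="1"/>
<text x="294.00" y="197.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="369.00" y1="182.00" x2="369.00" y2="186.00" stroke="#333333" stroke-width="1"/>
<text x="369.00" y="197.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">12.5</text>
<line x1="444.00" y1="182.00" x2="444.00" y2="186.00" stroke="#333333" stroke-width="1"/>
<text x="444.00" y="197.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">25</text>
<line x1="462.00" y1="182.00" x2="612.00" y2="182.00" stroke="#333333" stroke-width="1"/>
<line x1="462.00" y1="182.00" x2="462.00" y2="186.00" stroke="#333333" stroke-width="1"/>
<text x="462.00" y="197.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="537.00" y1="182.00" x2="537.00" y2="186.00" stroke="#333333" stroke-width="1"/>
<text x="537.00" y="197.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">12.5</text>
<line x1="612.00" y1="182.00" x2="612.00" y2="186.00" stroke="#333333" stroke-width="1"/>
<text x="612.00" y="197.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">25</text>
<text x="294.00" y="209.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" font-style="italic">odds ratio</text>
</svg>
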