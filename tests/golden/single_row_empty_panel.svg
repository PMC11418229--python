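<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="458.00" height="98.00" viewBox="0 0 458.00 98.00">
<rect x="0" y="0" width="458.00" height="98.00" fill="#ffffff"/>
<text x="369.00" y="28.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">only</text>
<text x="14.00" y="55.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">root process</text>
<line x1="294.00" y1="51.00" x2="444.00" y2="51.00" stroke="#eeeeee" stroke-width="1"/>
<line x1="294.00" y1="68.00" x2="444.00" y2="68.00" stroke="#333333" stroke-width="1"/>
<line x1="294.00" y1="68.00" x2="294.00" y2="72.00" stroke="#333333" stroke-width="1"/>
<text x="294.00" y="83.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="369.00" y1="68.00" x2="369.00" y2="72.00" stroke="#333333" stroke-width="1"/>
<text x="369.00" y="83.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0.5</text>
<line x1="444.00" y1="68.00" x2="444.00" y2="72.00" stroke="#333333" stroke-width="1"/>
<text x="444.00" y="83.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">1</text>
<text x="294.00" y="95.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" font-style="italic">fold change</text>
</svg>
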