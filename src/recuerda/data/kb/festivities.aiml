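<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="festivities" description="festividades que le gusta celebrar">
    <category role="trigger">
      <pattern>FIESTA</pattern>
      <template><random>
        <li>¡Las fiestas son pura alegría! ¿Es cierto que te encanta <get name="festividad_favorita"/>?</li>
        <li>¿Qué festividad celebras con más gusto?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ FIESTA</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>FIESTA _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ FIESTA _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>FIESTAS</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ FIESTAS</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>FIESTAS _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ FIESTAS _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>NAVIDAD</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ NAVIDAD</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>NAVIDAD _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ NAVIDAD _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>FESTIVIDAD</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ FESTIVIDAD</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>FESTIVIDAD _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ FESTIVIDAD _</pattern>
      <template><srai>FIESTA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué festejo! ¿Cómo celebrabas <get name="festividad_favorita"/>?</li>
        <li>¿Qué comida preparaban para <get name="festividad_favorita"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Entiendo. ¿Qué celebración te trae recuerdos bonitos?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Las celebraciones unen a todos. ¿Me platicas de una fiesta inolvidable?</li>
        <li>Las fiestas llenan la casa de vida. ¿Cuál esperabas cada año?</li>
      </random></template>
    </category>
  </topic>
</aiml>
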