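<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="beverages" description="bebidas preferidas del paciente">
    <category role="trigger">
      <pattern>BEBIDA</pattern>
      <template><random>
        <li>¿Es verdad que tu bebida preferida es <get name="bebida_favorita"/>?</li>
        <li>¿Qué bebida disfrutas en un día tranquilo?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ BEBIDA</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BEBIDA _</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BEBIDA _</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BEBIDAS</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BEBIDAS</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>BEBIDAS _</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ BEBIDAS _</pattern>
      <template><srai>BEBIDA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Refrescante! ¿En qué momentos tomabas <get name="bebida_favorita"/>?</li>
        <li>¿Con quién compartías <get name="bebida_favorita"/>?</li>
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
      <template>Está bien. ¿Qué te gusta tomar entonces?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Una buena bebida acompaña la plática. ¿Cuál prefieres?</li>
        <li>Un cafecito o un agua fresca siempre caen bien. ¿Qué tomabas tú?</li>
      </random></template>
    </category>
  </topic>
</aiml>
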